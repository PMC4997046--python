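"""Multi-channel image stack container.

All physical geometry in this package is expressed in micrometres.  Voxel
indices are 0-based ``(z, y, x)`` and the physical coordinate of a voxel is
``index * voxel_size``, measured at the voxel centre.  Channels are named;
by convention channel ``"tubulin"`` carries the microtubule signal and
``"dna"`` the chromosome signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

TUBULIN = "tubulin"
DNA = "dna"


@dataclass
class ImageStack:
    """A 3D ``(z, y, x)`` or 4D ``(t, z, y, x)`` multi-channel intensity image.

    Parameters
    ----------
    channels : dict
        Ordered mapping of channel name to a non-negative intensity array.
        All channels must share one shape, either 3D or 4D.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in micrometres.
    time_step : float, optional
        Frame interval in minutes; required for 4D stacks.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    time_step: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("stack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) not in (3, 4):
            raise ValidationError("stack must be 3D (z,y,x) or 4D (t,z,y,x)")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValidationError(f"negative intensities in channel {name!r}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths (dz,dy,dx)")
        if self.ndim == 4 and self.time_step is None:
            raise ValidationError("4D stacks require a time_step in minutes")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_timepoints(self) -> int:
        if self.ndim != 4:
            raise ValidationError("not a time series")
        return self.shape[0]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ValidationError(
                f"no channel {name!r}; have {list(self.channels)}"
            ) from None

    def frame(self, t: int) -> "ImageStack":
        """Extract one 3D time point from a 4D stack."""
        if self.ndim != 4:
            raise ValidationError("frame() only applies to 4D stacks")
        return ImageStack(
            channels={k: v[t] for k, v in self.channels.items()},
            voxel_size=self.voxel_size,
            meta=dict(self.meta),
        )

    def frames(self):
        """Iterate the 3D frames of a 4D stack."""
        for t in range(self.n_timepoints):
            yield self.frame(t)

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Convert ``(n, 3)`` voxel indices to micrometre coordinates."""
        return np.asarray(indices, dtype=float) * np.asarray(self.voxel_size)
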