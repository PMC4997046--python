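"""File I/O: OME-TIFF stacks and FASTA amplicons.

Stacks are written as OME-TIFF so that voxel size, channel names and the
frame interval travel with the pixels; the round trip preserves voxel
values bit-exactly.  Axis order and calibration can be overridden for
foreign files whose metadata is absent or ambiguous.
"""

from __future__ import annotations


import numpy as np
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .stack import ImageStack
from .synthetic import AmpliconSpec


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with physical calibration."""
    path = str(path)
    names = list(stack.channel_names)
    arrs = [stack.channels[n] for n in names]
    if stack.ndim == 3:
        data = np.stack(arrs, axis=0)  # (C, Z, Y, X)
        axes = "CZYX"
    else:
        data = np.stack(arrs, axis=1)  # (T, C, Z, Y, X)
        axes = "TCZYX"
    dz, dy, dx = stack.voxel_size
    metadata = {
        "axes": axes,
        "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": dy, "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": dx, "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": names},
    }
    if stack.time_step is not None:
        metadata["TimeIncrement"] = float(stack.time_step)
        metadata["TimeIncrementUnit"] = "min"
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def _pixels_meta(tf: tifffile.TiffFile) -> dict:
    if tf.ome_metadata is None:
        return {}
    meta = tifffile.xml2dict(tf.ome_metadata)
    image = meta.get("OME", {}).get("Image", {})
    if isinstance(image, list):
        image = image[0]
    return image.get("Pixels", {})


def read_stack(
    path,
    axes: str | None = None,
    voxel_size=None,
    channel_names=None,
    time_step: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Axis order is taken from the file's series metadata unless ``axes`` is
    given (a string over C, Z, Y, X and optionally T).  Voxel size, channel
    names and (for time series) the frame interval come from OME metadata;
    absent metadata must be supplied explicitly or an error names the
    missing argument (CLI flag ``--voxel-size`` / ``--time-step`` /
    ``--axes``).
    """
    path = str(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
        pixels = _pixels_meta(tf)

    axes = (axes or file_axes).upper()
    if len(axes) != data.ndim or set(axes) - set("TCZYX") or len(set(axes)) != len(axes):
        raise ValidationError(
            f"cannot resolve axis order {axes!r} for a {data.ndim}D array; "
            "pass axes= (--axes) with a permutation of [T]CZYX")
    for required in "YX":
        if required not in axes:
            raise ValidationError(f"axis {required!r} missing from {axes!r}")

    # normalise to (T, C, Z, Y, X), inserting singleton axes
    full = "TCZYX"
    for a in full:
        if a not in axes:
            data = np.expand_dims(data, axis=0)
            axes = a + axes
    data = np.transpose(data, [axes.index(a) for a in full])
    n_t, n_c = data.shape[:2]

    if voxel_size is None:
        try:
            voxel_size = (float(pixels["PhysicalSizeZ"]),
                          float(pixels["PhysicalSizeY"]),
                          float(pixels["PhysicalSizeX"]))
        except KeyError:
            raise ValidationError(
                "no voxel-size metadata in file; pass voxel_size= "
                "(--voxel-size DZ DY DX, in µm)") from None

    if channel_names is None:
        chan = pixels.get("Channel")
        if chan is not None:
            if isinstance(chan, dict):
                chan = [chan]
            names = [c.get("Name") for c in chan]
            if all(names) and len(names) == n_c:
                channel_names = names
        if channel_names is None:
            channel_names = ["tubulin", "dna"][:n_c] if n_c <= 2 else [
                f"channel{i}" for i in range(n_c)]
    if len(channel_names) != n_c:
        raise ValidationError(
            f"{n_c} channels in file but {len(channel_names)} names given")

    is_4d = n_t > 1
    if is_4d and time_step is None:
        if "TimeIncrement" in pixels:
            time_step = float(pixels["TimeIncrement"])
        else:
            raise ValidationError(
                "time series without frame-interval metadata; pass "
                "time_step= (--time-step, minutes)")

    channels = {}
    for i, name in enumerate(channel_names):
        arr = data[:, i] if is_4d else data[0, i]
        channels[name] = arr
    return ImageStack(channels=channels, voxel_size=voxel_size,
                      time_step=time_step if is_4d else None)


# ---------------------------------------------------------------------------
# FASTA


def write_amplicons(amplicons: list[AmpliconSpec], path) -> None:
    """Write amplicons to FASTA; the header carries assay and true allele."""
    records = []
    for i, amp in enumerate(amplicons):
        records.append(SeqRecord(
            Seq(amp.sequence),
            id=f"amplicon_{i + 1}",
            description=f"assay={amp.assay} allele={amp.allele_truth}"))
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
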