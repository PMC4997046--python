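"""Seeded synthetic data emulating a maize meiotic-spindle imaging study.

The generators produce, with known ground truth:

* 3D two-channel metaphase meiocyte stacks (tubulin + chromosomes) with a
  controllable pole-divergence parameter, multi-spindle and tripolar layouts;
* 4D anaphase time-lapse series (default 5-min frame interval, 20 μm axial
  range at 1 μm steps, mimicking widefield acquisition of live meiocytes);
* qPCR Ct tables with prescribed true relative expression;
* per-plant binomial count tables (pollen viability, tetrad scoring);
* amplicon sequences carrying — or free of — diagnostic restriction sites.

Every generator is a pure function of its parameters and seed.

Geometry model
--------------
A spindle is a bundle of fibers running from points sampled uniformly on the
metaphase-plate disc toward each pole.  The ``divergence`` parameter in
[0, 1] linearly interpolates the fiber envelope between a cone (0: fibers
meet at a pole point, tightly focused) and a cylinder (1: fibers stay
parallel, fully divergent poles).  At axial fraction ``f`` of the
plate-to-pole distance the envelope radius is ``R * ((1 - f) + f * d)``
where ``R`` is the plate radius and ``d`` the divergence.  The chromosome
mass is a uniform oblate ellipsoid of diameter ``plate_width_true`` centred
on the plate.  Rendering applies an anisotropic Gaussian PSF, optional
Poisson shot noise on ``signal × photon_scale`` photons, and additive
Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import GenerationError, GeometryError, ValidationError
from .genotyping import ASSAYS, Assay, EnzymeSpec, find_sites
from .stack import DNA, TUBULIN, ImageStack

#: Default voxel grid: 20 slices at 1 μm covering a 20 μm Z range, with
#: finer lateral sampling as in real widefield stacks.
DEFAULT_SHAPE = (20, 96, 160)
DEFAULT_VOXEL_SIZE = (1.0, 0.2, 0.2)

_AXIS_X = np.array([0.0, 0.0, 1.0])  # +x in (z, y, x) component order


@dataclass(frozen=True)
class Optics:
    """Image-formation parameters.

    ``psf_sigma`` is the Gaussian PSF sigma per axis (z, y, x) in μm;
    ``photon_scale`` converts unit signal to expected photons; shot noise is
    Poisson on ``signal × photon_scale + background`` and ``read_noise_sd``
    is the camera's additive Gaussian noise in the same counts.
    """

    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)
    background: float = 10.0
    photon_scale: float = 80.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True

    @classmethod
    def noiseless(cls, psf_sigma=(0.6, 0.25, 0.25), photon_scale=100.0) -> "Optics":
        """Deterministic optics: PSF blur only, no background or noise."""
        return cls(psf_sigma=psf_sigma, background=0.0,
                   photon_scale=photon_scale, read_noise_sd=0.0,
                   shot_noise=False)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero vector where a direction was expected")
    return v / n


def _orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``normal``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, helper))
    v = _unit(np.cross(normal, u))
    return u, v


def _default_plate_center(shape, voxel_size) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1) * np.asarray(voxel_size) / 2.0


@dataclass
class SpindleGroundTruth:
    """Generator parameters for one synthetic meiocyte, kept as ground truth.

    ``pole_positions`` holds ``n_spindles × n_poles_per_spindle`` points in
    μm, grouped by spindle; each spindle's plate centre is the centroid of
    its pole group.  ``plate_center`` is the first spindle's plate centre.
    """

    pole_positions: np.ndarray
    plate_center: np.ndarray
    plate_normal: np.ndarray
    plate_width_true: float
    half_length_true: float
    divergence: float
    n_spindles: int = 1
    n_poles_per_spindle: int = 2
    fiber_count: int = 5000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.pole_positions = np.atleast_2d(np.asarray(self.pole_positions, dtype=float))
        self.plate_center = np.asarray(self.plate_center, dtype=float)
        self.plate_normal = _unit(self.plate_normal)
        if not (self.half_length_true > 0 and self.plate_width_true > 0):
            raise ValidationError("half_length_true and plate_width_true must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValidationError(f"divergence must be in [0, 1], got {self.divergence}")
        if self.fiber_count < 1 or self.n_spindles < 1 or self.n_poles_per_spindle < 1:
            raise ValidationError("counts must be positive")
        expected = self.n_spindles * self.n_poles_per_spindle
        if len(self.pole_positions) != expected:
            raise ValidationError(
                f"expected {expected} pole positions, got {len(self.pole_positions)}"
            )
        if not np.all(np.isfinite(self.pole_positions)):
            raise ValidationError("pole positions must be finite")

    # -- constructors ------------------------------------------------------

    @classmethod
    def bipolar(cls, plate_center=None, axis=_AXIS_X, half_length: float = 12.0,
                plate_width: float = 10.0, divergence: float = 0.1,
                fiber_count: int = 5000, seed: int = 0,
                shape=DEFAULT_SHAPE, voxel_size=DEFAULT_VOXEL_SIZE) -> "SpindleGroundTruth":
        """A single bipolar spindle centred in the default grid."""
        axis = _unit(axis)
        if plate_center is None:
            plate_center = _default_plate_center(shape, voxel_size)
        plate_center = np.asarray(plate_center, dtype=float)
        poles = np.stack([plate_center + half_length * axis,
                          plate_center - half_length * axis])
        return cls(poles, plate_center, axis, plate_width, half_length,
                   divergence, 1, 2, fiber_count, seed)

    @classmethod
    def multi_spindle(cls, n_spindles: int = 2, gap: float = 5.0,
                      separation_axis=(0.0, 1.0, 0.0), plate_center=None,
                      axis=_AXIS_X, half_length: float = 8.0,
                      plate_width: float = 6.0, divergence: float = 0.1,
                      fiber_count: int = 5000, seed: int = 0,
                      shape=DEFAULT_SHAPE, voxel_size=DEFAULT_VOXEL_SIZE) -> "SpindleGroundTruth":
        """Parallel side-by-side spindles separated by ``gap`` μm of space."""
        axis = _unit(axis)
        sep = _unit(separation_axis)
        if plate_center is None:
            plate_center = _default_plate_center(shape, voxel_size)
        plate_center = np.asarray(plate_center, dtype=float)
        pitch = plate_width + gap  # centre-to-centre => edge gap ≈ gap
        offsets = (np.arange(n_spindles) - (n_spindles - 1) / 2.0) * pitch
        poles = []
        for off in offsets:
            c = plate_center + off * sep
            poles.append(c + half_length * axis)
            poles.append(c - half_length * axis)
        first_center = plate_center + offsets[0] * sep
        return cls(np.stack(poles), first_center, axis, plate_width,
                   half_length, divergence, n_spindles, 2, fiber_count, seed)

    @classmethod
    def tripolar(cls, plate_center=None, axis=_AXIS_X,
                 third_pole_axis=(0.0, 1.0, 0.0), half_length: float = 7.0,
                 plate_width: float = 6.0, divergence: float = 0.0,
                 fiber_count: int = 5000, seed: int = 0,
                 shape=DEFAULT_SHAPE, voxel_size=DEFAULT_VOXEL_SIZE) -> "SpindleGroundTruth":
        """One spindle with a third pole branching off perpendicular."""
        axis = _unit(axis)
        third = _unit(third_pole_axis)
        if plate_center is None:
            plate_center = _default_plate_center(shape, voxel_size)
        plate_center = np.asarray(plate_center, dtype=float)
        # the plate centre must remain the pole-group centroid
        raw = np.stack([half_length * axis, -half_length * axis, half_length * third])
        poles = plate_center + raw - raw.mean(axis=0)
        center = poles.mean(axis=0)
        return cls(poles, center, axis, plate_width, half_length,
                   divergence, 1, 3, fiber_count, seed)

    # -- derived geometry --------------------------------------------------

    def pole_groups(self) -> list[np.ndarray]:
        k = self.n_poles_per_spindle
        return [self.pole_positions[i * k:(i + 1) * k] for i in range(self.n_spindles)]

    def spindle_plate_centers(self) -> list[np.ndarray]:
        return [g.mean(axis=0) for g in self.pole_groups()]


@dataclass
class SpindleSignalMasks:
    """Pre-blur, pre-noise voxel labels of the rendered structures."""

    tubulin: np.ndarray  # bool, True where fiber signal was deposited
    dna: np.ndarray      # bool, True inside a chromosome mass


def _check_fits(points_um: np.ndarray, shape, voxel_size, psf_sigma) -> None:
    extent = (np.asarray(shape, dtype=float) - 1) * np.asarray(voxel_size)
    margin = 3.0 * np.asarray(psf_sigma)
    lo = points_um.min(axis=0)
    hi = points_um.max(axis=0)
    if np.any(lo < margin) or np.any(hi > extent - margin):
        raise GeometryError(
            "geometry does not fit the voxel grid with a 3·psf_sigma margin: "
            f"structure spans {lo}..{hi} μm, usable {margin}..{extent - margin} μm"
        )


def _deposit_points(grid: np.ndarray, points_um: np.ndarray, weights,
                    voxel_size) -> None:
    idx = np.rint(points_um / np.asarray(voxel_size)).astype(int)
    shape = np.asarray(grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[ok]
    w = np.broadcast_to(np.asarray(weights, dtype=float), len(points_um))[ok]
    np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), w)


def _fiber_points(truth: SpindleGroundTruth, rng: np.random.Generator,
                  step: float) -> np.ndarray:
    """Sample points along every fiber polyline; returns (n, 3) μm."""
    radius = truth.plate_width_true / 2.0
    u, v = _orthonormal_basis(truth.plate_normal)
    all_points = []
    weights = []
    for poles, center in zip(truth.pole_groups(), truth.spindle_plate_centers()):
        # fiber anchor points: uniform over the plate disc
        r = radius * np.sqrt(rng.random(truth.fiber_count))
        theta = rng.random(truth.fiber_count) * 2 * np.pi
        offsets = r[:, None] * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        starts = center + offsets
        for pole in poles:
            w = _unit(pole - center)
            # at the pole, the residual lateral offset is divergence × the
            # anchor offset (component perpendicular to the branch direction)
            perp = offsets - (offsets @ w)[:, None] * w[None, :]
            ends = pole + truth.divergence * perp
            seg_len = float(np.linalg.norm(pole - center))
            n_steps = max(2, int(math.ceil(seg_len / step)) + 1)
            # per-fiber random sampling phase: with a shared phase all fibers
            # hit the same axial voxel bins and the slab-integrated intensity
            # acquires a strong sawtooth
            phase = rng.random(truth.fiber_count)
            f = (np.arange(n_steps)[None, :] + phase[:, None]) / n_steps
            pts = starts[:, None, :] * (1 - f)[..., None] + ends[:, None, :] * f[..., None]
            all_points.append(pts.reshape(-1, 3))
            weights.append(np.full(len(f.ravel()), seg_len / n_steps))
    return np.concatenate(all_points, axis=0), np.concatenate(weights)


def _ellipsoid_indicator(shape, voxel_size, center, normal, radius,
                         half_thickness) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) * d for n, d in zip(shape, voxel_size)),
                             indexing="ij")
    d = np.stack([zz, yy, xx], axis=-1) - np.asarray(center)
    ax = d @ np.asarray(normal)
    rad_sq = np.einsum("...i,...i", d, d) - ax ** 2
    return (ax / half_thickness) ** 2 + rad_sq / radius ** 2 <= 1.0


def _apply_optics(signal: np.ndarray, optics: Optics, voxel_size,
                  rng: np.random.Generator) -> np.ndarray:
    sigma_vox = np.asarray(optics.psf_sigma) / np.asarray(voxel_size)
    blurred = gaussian_filter(signal, sigma=sigma_vox)
    expected = blurred * optics.photon_scale + optics.background
    if optics.shot_noise:
        image = rng.poisson(expected).astype(float)
    else:
        image = expected
    if optics.read_noise_sd > 0:
        image = image + rng.normal(0.0, optics.read_noise_sd, size=image.shape)
    return np.clip(image, 0.0, None)


def generate_spindle_stack(
    truth: SpindleGroundTruth,
    optics: Optics | None = None,
    shape=DEFAULT_SHAPE,
    voxel_size=DEFAULT_VOXEL_SIZE,
    *,
    chromosome_offset=(0.0, 0.0, 0.0),
    plate_thickness: float = 2.0,
    return_masks: bool = False,
):
    """Render a two-channel metaphase stack from ground-truth geometry.

    Returns ``(stack, truth)``, or ``(stack, truth, masks)`` with
    ``return_masks=True`` where ``masks`` carries the pre-blur voxel labels
    for segmentation-recovery tests.  Identical inputs and seed give
    bitwise-identical stacks.

    ``chromosome_offset`` (μm) displaces the chromosome mass from the plate
    centre, emulating poor congression.
    """
    optics = optics or Optics()
    rng = np.random.default_rng(truth.rng_seed)
    voxel_size = tuple(float(s) for s in voxel_size)

    rim = []
    u, v = _orthonormal_basis(truth.plate_normal)
    radius = truth.plate_width_true / 2.0
    for c in truth.spindle_plate_centers():
        rim += [c + radius * u, c - radius * u, c + radius * v, c - radius * v]
    _check_fits(np.vstack([truth.pole_positions, rim]), shape, voxel_size,
                optics.psf_sigma)

    step = 0.5 * min(voxel_size)
    tub_signal = np.zeros(shape, dtype=float)
    pts, weights = _fiber_points(truth, rng, step)
    _deposit_points(tub_signal, pts, weights, voxel_size)

    dna_signal = np.zeros(shape, dtype=float)
    offset = np.asarray(chromosome_offset, dtype=float)
    for c in truth.spindle_plate_centers():
        dna_signal += _ellipsoid_indicator(shape, voxel_size, c + offset,
                                           truth.plate_normal, radius,
                                           plate_thickness / 2.0)
    dna_signal = np.clip(dna_signal, 0.0, 1.0)

    masks = SpindleSignalMasks(tubulin=tub_signal > 0, dna=dna_signal > 0)

    stack = ImageStack(
        channels={
            TUBULIN: _apply_optics(tub_signal, optics, voxel_size, rng),
            DNA: _apply_optics(dna_signal, optics, voxel_size, rng),
        },
        voxel_size=voxel_size,
        meta={"rng_seed": truth.rng_seed, "divergence": truth.divergence},
    )
    if return_masks:
        return stack, truth, masks
    return stack, truth


# ---------------------------------------------------------------------------
# anaphase time-lapse


@dataclass
class AnaphaseGroundTruth:
    """Per-frame ground truth for a simulated anaphase movie."""

    chromosome_mass_centroids: np.ndarray  # (T, 2, 3) μm
    spindle_centroid: np.ndarray           # (T, 3) μm
    poleward_speed_true: float             # μm/min per mass
    anaphase_onset: float                  # minutes
    times: np.ndarray                      # (T,) minutes

    def __post_init__(self) -> None:
        if self.poleward_speed_true < 0:
            raise ValidationError("poleward speed must be non-negative")
        if not np.all(np.isfinite(self.chromosome_mass_centroids)):
            raise ValidationError("centroids must be finite")


def generate_anaphase_series(
    truth: SpindleGroundTruth,
    speed: float,
    n_timepoints: int = 6,
    time_step: float = 5.0,
    optics: Optics | None = None,
    shape=DEFAULT_SHAPE,
    voxel_size=DEFAULT_VOXEL_SIZE,
    *,
    anaphase_onset: float = 0.0,
    initial_separation: float = 3.0,
    mass_radius: float = 3.0,
    mass_half_thickness: float = 0.75,
):
    """Render a 4D two-channel anaphase movie with known mass trajectories.

    Two chromosome masses start ``initial_separation`` μm apart on the
    spindle axis and, from ``anaphase_onset`` minutes, move poleward at
    ``±speed`` μm/min.  The tubulin channel shows the (static) spindle.
    Returns ``(stack4d, anaphase_truth)``.
    """
    if speed < 0:
        raise ValidationError("speed must be non-negative")
    if n_timepoints < 2:
        raise ValidationError("need at least two time points")
    optics = optics or Optics()
    rng = np.random.default_rng(truth.rng_seed)
    voxel_size = tuple(float(s) for s in voxel_size)

    axis = truth.plate_normal
    center = truth.plate_center
    times = np.arange(n_timepoints, dtype=float) * time_step
    travel = np.maximum(0.0, times - anaphase_onset) * speed
    half_sep = initial_separation / 2.0 + travel
    centroids = np.stack([
        np.stack([center + h * axis for h in half_sep]),
        np.stack([center - h * axis for h in half_sep]),
    ], axis=1)  # (T, 2, 3)

    _check_fits(np.vstack([truth.pole_positions, centroids.reshape(-1, 3)]),
                shape, voxel_size, optics.psf_sigma)

    # fiber geometry is frozen once so frames differ only by noise and the
    # chromosome positions
    step = 0.5 * min(voxel_size)
    tub_signal = np.zeros(shape, dtype=float)
    fiber_pts, fiber_w = _fiber_points(truth, rng, step)
    _deposit_points(tub_signal, fiber_pts, fiber_w, voxel_size)

    tub_frames, dna_frames = [], []
    for t in range(n_timepoints):
        dna_signal = np.zeros(shape, dtype=float)
        for mass in range(2):
            dna_signal += _ellipsoid_indicator(
                shape, voxel_size, centroids[t, mass], axis,
                mass_radius, mass_half_thickness)
        dna_signal = np.clip(dna_signal, 0.0, 1.0)
        tub_frames.append(_apply_optics(tub_signal, optics, voxel_size, rng))
        dna_frames.append(_apply_optics(dna_signal, optics, voxel_size, rng))

    stack = ImageStack(
        channels={TUBULIN: np.stack(tub_frames), DNA: np.stack(dna_frames)},
        voxel_size=voxel_size,
        time_step=float(time_step),
        meta={"rng_seed": truth.rng_seed, "speed": speed},
    )
    ana_truth = AnaphaseGroundTruth(
        chromosome_mass_centroids=centroids,
        spindle_centroid=np.tile(center, (n_timepoints, 1)),
        poleward_speed_true=float(speed),
        anaphase_onset=float(anaphase_onset),
        times=times,
    )
    return stack, ana_truth


# ---------------------------------------------------------------------------
# qPCR Ct tables

REFERENCE_CT_BASELINE = 20.0
TARGET_CT_BASELINE = 24.0


def generate_ct_table(
    design: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for a target gene and a reference gene.

    ``design`` maps genotype label to its true expression relative to the
    calibrator (the genotype with expression 1.0 unless given explicitly).
    The target Ct is offset by ``-log2(expression)`` cycles relative to the
    calibrator's target baseline; Gaussian cycle noise of ``noise_sd`` is
    added to every well.

    Returns a tidy frame with columns ``sample_id, genotype, gene
    ("target"/"reference"), ct, replicate``.
    """
    if not design:
        raise ValidationError("design must name at least one genotype")
    for g, expr in design.items():
        if not expr > 0:
            raise ValidationError(f"true relative expression must be positive ({g}: {expr})")
    if calibrator is None:
        ones = [g for g, e in design.items() if e == 1.0]
        calibrator = ones[0] if ones else next(iter(design))
    if calibrator not in design:
        raise ValidationError(f"calibrator {calibrator!r} not in design")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, expr in design.items():
        rel = expr / design[calibrator]
        for rep in range(n_replicates):
            sample = f"{genotype}_{rep + 1}"
            target_ct = TARGET_CT_BASELINE - math.log2(rel)
            rows.append((sample, genotype, "target",
                         target_ct + rng.normal(0.0, noise_sd) if noise_sd else target_ct,
                         rep + 1))
            ref_ct = REFERENCE_CT_BASELINE
            rows.append((sample, genotype, "reference",
                         ref_ct + rng.normal(0.0, noise_sd) if noise_sd else ref_ct,
                         rep + 1))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "gene", "ct", "replicate"])


# ---------------------------------------------------------------------------
# count tables


def generate_count_table(
    design: dict[str, float],
    n_scored: int = 500,
    n_plants: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant binomial scoring counts (e.g. viable pollen of 500 scored).

    ``design`` maps genotype label to the per-grain positive probability.
    """
    for g, p in design.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"probability out of [0,1] for {g}: {p}")
    if n_scored < 1 or n_plants < 1:
        raise ValidationError("n_scored and n_plants must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, p in design.items():
        for i in range(n_plants):
            k = int(rng.binomial(n_scored, p))
            rows.append((f"{genotype}_p{i + 1}", genotype, n_scored, k))
    return pd.DataFrame(rows, columns=["plant_id", "genotype", "n_scored", "n_positive"])


# ---------------------------------------------------------------------------
# amplicon sequences

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class AmpliconSpec:
    """A synthetic PCR product with known digest behaviour."""

    sequence: str
    assay: str
    allele_truth: str  # "cut-allele" | "uncut-allele"
    cut_positions: tuple[int, ...]


def _resolve_assay(assay) -> Assay:
    if isinstance(assay, Assay):
        return assay
    try:
        return ASSAYS[assay]
    except KeyError:
        raise ValidationError(f"unknown assay {assay!r}; have {list(ASSAYS)}") from None


def generate_amplicons(
    assay,
    allele: str,
    length: int | None = None,
    cut_positions=None,
    seed: int = 0,
    max_retries: int = 100,
) -> AmpliconSpec:
    """Generate a random amplicon whose digest pattern is fully prescribed.

    The sequence contains the assay enzyme's recognition site so that
    top-strand cleavage occurs exactly at each requested ``cut_position``
    and nowhere else; the uncut allele contains zero occurrences.  Raises
    :class:`GenerationError` if the placement is impossible (overlapping
    sites) or no site-free filler is found within ``max_retries``.
    """
    assay = _resolve_assay(assay)
    enzyme: EnzymeSpec = assay.enzyme
    if allele not in ("cut-allele", "uncut-allele"):
        raise ValidationError("allele must be 'cut-allele' or 'uncut-allele'")
    if length is None:
        length = assay.amplicon_length
    if cut_positions is None:
        if allele == "cut-allele":
            # derive the canonical cut positions from the expected fragments
            cut_positions = tuple(np.cumsum(assay.cut_fragments[:-1]).tolist())
        else:
            cut_positions = ()
    cut_positions = tuple(sorted(int(c) for c in cut_positions))
    if allele == "uncut-allele" and cut_positions:
        raise ValidationError("uncut allele cannot carry cut positions")
    if allele == "cut-allele" and not cut_positions:
        raise ValidationError("cut allele needs at least one cut position")

    k = len(enzyme.site)
    site = np.frombuffer(enzyme.site.encode(), dtype="S1")
    starts = []
    for c in cut_positions:
        if not 0 < c < length:
            raise ValidationError(f"cut position {c} not strictly inside (0, {length})")
        s = c - enzyme.cut_offset
        if s < 0 or s + k > length:
            raise GenerationError(
                f"site for cut at {c} does not fit inside the amplicon")
        starts.append(s)
    for a, b in zip(starts, starts[1:]):
        if b < a + k:
            raise GenerationError(f"recognition sites at {a} and {b} overlap")
    protected = np.zeros(length, dtype=bool)
    for s in starts:
        protected[s:s + k] = True

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        seq = _BASES[rng.integers(0, 4, size=length)].copy()
        for s in starts:
            seq[s:s + k] = site
        ok = False
        for _ in range(20):
            text = seq.tobytes().decode()
            extra = [p - enzyme.cut_offset for p in find_sites(text, enzyme)
                     if p not in cut_positions]
            if not extra:
                ok = True
                break
            for o in extra:
                mutable = [p for p in range(o, o + k) if not protected[p]]
                if not mutable:
                    break
                p = int(rng.choice(mutable))
                current = seq[p]
                choices = _BASES[_BASES != current]
                seq[p] = rng.choice(choices)
        if ok:
            text = seq.tobytes().decode()
            assert tuple(find_sites(text, enzyme)) == cut_positions
            return AmpliconSpec(sequence=text, assay=assay.name,
                                allele_truth=allele, cut_positions=cut_positions)
    raise GenerationError(
        f"could not place {len(cut_positions)} site(s) without extras in "
        f"{max_retries} attempts")
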