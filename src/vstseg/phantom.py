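"""Synthetic labelled cardiac phantoms.

Generates 2-D slices or 3-D volumes containing the six segmented structures
(LVM, LV, LA, RV, RA, AO) as simple analytic shapes with the topology and
intensity ordering the segmentation method relies on: the myocardium (LVM)
forms a closed shell around the LV blood pool, and the contrast-filled
chambers and aorta are brighter than the myocardium.  Structure volumes for
3-D phantoms are drawn from literature ranges of manual whole-heart
segmentation; geometry is jittered per seed so a dataset of phantoms has
independently varying shapes, while ground-truth masks and volumes are exact
by construction.

Realism is a non-goal: these phantoms exist so that every downstream module
(saliency, network, training, evaluation) is testable without patient data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, LabelMask
from .labels import AO, LA, LV, LVM, RA, RV, STRUCTURES, LABEL_NAMES


class PhantomSizingError(ValueError):
    """A structure cannot be packed into the grid at the requested volume."""

    def __init__(self, structure: int, reason: str):
        self.structure = structure
        super().__init__(f"cannot place structure {LABEL_NAMES[structure]}: {reason}")


#: default per-structure 3-D volume ranges in ml (manual whole-heart
#: segmentation ranges reported for 12 contrast CT cases)
DEFAULT_VOLUME_RANGES_ML: dict[int, tuple[float, float]] = {
    LVM: (65.4, 128.8),
    LV: (45.1, 173.5),
    LA: (38.4, 98.9),
    RV: (62.9, 198.9),
    RA: (51.1, 114.2),
    AO: (21.4, 48.8),
}

#: default mean intensities on a [0, 1] scale; chambers/aorta brighter than
#: myocardium, encoding the contrast-agent ordering without claiming HU accuracy
DEFAULT_INTENSITIES: dict[int, float] = {
    LVM: 0.35,
    LV: 0.85,
    LA: 0.65,
    RV: 0.60,
    RA: 0.55,
    AO: 0.90,
}

# relative centre positions (fractions of each axis) for a four-chamber-like
# layout; axis 2 (3-D) centres everything mid-volume except the aorta
_CENTRES_2D: dict[int, tuple[float, float]] = {
    LV: (0.60, 0.37),
    LA: (0.33, 0.38),
    RV: (0.57, 0.63),
    RA: (0.32, 0.63),
    AO: (0.46, 0.50),
}

# 3-D in-plane centres: the right heart is nudged inward because its large
# literature volume ranges otherwise push it into the grid border once the
# left heart has claimed the centre of the volume
_CENTRES_3D: dict[int, tuple[float, float]] = {
    LV: (0.60, 0.37),
    LA: (0.33, 0.40),
    RV: (0.57, 0.58),
    RA: (0.34, 0.60),
    AO: (0.46, 0.50),
}

# relative axial (axis-2) centre positions for 3-D volumes: atria sit below
# the ventricular plane, so structures do not all compete in one mid-volume
# slab
_Z_CENTRES_3D: dict[int, float] = {
    LV: 0.52,
    LA: 0.38,
    RV: 0.56,
    RA: 0.40,
    AO: 0.50,
}

# relative in-plane semi-axis ratios (unit scale; absolute size comes from the
# requested voxel count, not from these)
_AXES_2D: dict[int, tuple[float, float]] = {
    LV: (1.0, 1.0),
    LA: (1.1, 0.9),
    RV: (0.85, 1.15),
    RA: (1.0, 1.0),
    AO: (1.0, 1.0),
}

#: fraction of a 2-D grid occupied by all six structures together
FOREGROUND_FRACTION_2D = 0.35


@dataclass
class PhantomSpec:
    """Parameters of one phantom; identical spec + seed gives identical bytes."""

    seed: int = 0
    grid_size: tuple[int, ...] = (64, 64)
    spacing_mm: tuple[float, ...] | None = None
    structure_volume_ranges_ml: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_RANGES_ML)
    )
    chamber_intensity: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sd: float = 0.05
    #: (label_a, label_b, blur width in voxels); blur acts on the image only
    boundary_blur_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid_size = tuple(int(s) for s in self.grid_size)
        if len(self.grid_size) not in (2, 3):
            raise ValueError("grid_size must be 2-D or 3-D")
        if self.spacing_mm is None:
            self.spacing_mm = (3.0, 3.0) if len(self.grid_size) == 2 else (2.5, 2.5, 2.5)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != len(self.grid_size):
            raise ValueError("spacing_mm length must match grid_size")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for k, (lo, hi) in self.structure_volume_ranges_ml.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad volume range for label {k}: ({lo}, {hi})")

    @property
    def ndim(self) -> int:
        return len(self.grid_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class PhantomSample:
    """One generated phantom: image, exact mask, and exact per-label volumes."""

    image: ImageGrid
    mask: LabelMask
    true_volumes_ml: dict[int, float]
    spec: PhantomSpec | None = None


def _ellipsoid_metric(shape, spacing, centre_vox, axes, rng, jitter=True):
    """Squared anisotropic distance (mm-scaled) from a jittered centre."""
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    m = np.zeros(shape, dtype=np.float64)
    for ax, (c, a, sp, n) in enumerate(zip(centre_vox, axes, spacing, shape)):
        cj = c + (rng.uniform(-0.015, 0.015) * n if jitter else 0.0)
        aj = a * (rng.uniform(0.92, 1.08) if jitter else 1.0)
        m += ((coords[ax] - cj) * sp / aj) ** 2
    return m


def _grow_region(metric, unclaimed, n_target, label, seed_region=None):
    """Claim n_target unclaimed voxels in metric order, frontier by frontier.

    Growth only ever claims voxels face-adjacent to the region grown so far
    (or to ``seed_region``, used to grow the LVM shell around the LV), so the
    claimed set is connected by construction even when it must deform around
    previously placed structures.
    """
    struct = ndimage.generate_binary_structure(metric.ndim, 1)
    if seed_region is None:
        free = np.flatnonzero(unclaimed.ravel())
        if free.size == 0:
            raise PhantomSizingError(label, "no free voxels")
        start = free[np.argmin(metric.ravel()[free])]
        region = np.zeros(metric.shape, dtype=bool)
        region.ravel()[start] = True
        claimed = [start]
        support = region
    else:
        region = np.zeros(metric.shape, dtype=bool)
        claimed = []
        support = seed_region.copy()
    flat_metric = metric.ravel()
    while len(claimed) < n_target:
        frontier = ndimage.binary_dilation(support | region, structure=struct)
        frontier &= unclaimed & ~region
        cand = np.flatnonzero(frontier.ravel())
        if cand.size == 0:
            raise PhantomSizingError(
                label, f"growth blocked at {len(claimed)}/{n_target} voxels"
            )
        take = min(cand.size, n_target - len(claimed))
        order = np.argsort(flat_metric[cand], kind="stable")[:take]
        chosen = cand[order]
        region.ravel()[chosen] = True
        claimed.extend(chosen.tolist())
    return np.asarray(claimed, dtype=np.intp)


def _check_structure(mask, label, ndim):
    sel = mask == label
    struct = ndimage.generate_binary_structure(ndim, 1)
    _, n_comp = ndimage.label(sel, structure=struct)
    if n_comp != 1:
        raise PhantomSizingError(label, f"structure split into {n_comp} components")
    # touching the grid border indicates the grid is too small for the volume
    border = np.zeros_like(sel)
    for ax in range(ndim):
        sl = [slice(None)] * ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if np.any(sel & border):
        raise PhantomSizingError(label, "structure reaches the grid border")


def _target_counts(spec: PhantomSpec, rng: np.random.Generator) -> dict[int, int]:
    vols = {
        k: rng.uniform(lo, hi) for k, (lo, hi) in spec.structure_volume_ranges_ml.items()
    }
    if spec.ndim == 3:
        counts = {k: int(round(v * 1000.0 / spec.voxel_volume_mm3)) for k, v in vols.items()}
    else:
        # 2-D slices: apportion a fixed foreground area by the sampled volume mix
        total_fg = FOREGROUND_FRACTION_2D * float(np.prod(spec.grid_size))
        vsum = sum(vols.values())
        counts = {k: int(round(total_fg * v / vsum)) for k, v in vols.items()}
    n_total = int(np.prod(spec.grid_size))
    if sum(counts.values()) > 0.55 * n_total:
        worst = max(counts, key=counts.get)
        raise PhantomSizingError(worst, "requested volumes exceed grid capacity")
    for k, c in counts.items():
        if c < 1:
            raise PhantomSizingError(k, "requested volume smaller than one voxel")
    return counts


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one labelled phantom from a :class:`PhantomSpec`.

    Structures are grown voxel-by-voxel in order of an anisotropic ellipsoid
    metric until they reach their target voxel count, so the realised voxel
    count (and hence the reported volume) matches the target to within half a
    voxel.  The LVM is grown around the already-placed LV, which yields a
    closed shell.  Blur across listed label-pair boundaries perturbs the image
    only; the mask stays crisp.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_size
    ndim = spec.ndim
    spacing = spec.spacing_mm
    counts = _target_counts(spec, rng)

    mask = np.zeros(shape, dtype=np.int64)
    unclaimed = np.ones(shape, dtype=bool)

    def centre_axes(label):
        cy, cx = (_CENTRES_2D if ndim == 2 else _CENTRES_3D)[label]
        ay, ax_ = _AXES_2D[label]
        if ndim == 2:
            return (cy * shape[0], cx * shape[1]), (ay, ax_)
        # 3-D: per-structure axial centre; aorta elongated along axis 2
        az = 3.0 if label == AO else (ay + ax_) / 2.0
        cz = _Z_CENTRES_3D[label]
        return (cy * shape[0], cx * shape[1], cz * shape[2]), (ay, ax_, az)

    lv_metric = None
    order = (LV, LVM, AO, LA, RV, RA)
    for label in order:
        if label == LVM:
            metric = lv_metric  # grow the shell outward around the LV pool
            idx = _grow_region(metric, unclaimed, counts[label], label,
                               seed_region=(mask == LV))
        else:
            c, a = centre_axes(label)
            metric = _ellipsoid_metric(shape, spacing, c, a, rng)
            if label == LV:
                lv_metric = metric
            idx = _grow_region(metric, unclaimed, counts[label], label)
        mask.ravel()[idx] = label
        unclaimed.ravel()[idx] = False
        _check_structure(mask, label, ndim)

    _check_shell(mask, ndim)

    image = np.zeros(shape, dtype=np.float64)
    for label, mean in spec.chamber_intensity.items():
        image[mask == label] = mean

    for a, b, width in spec.boundary_blur_pairs:
        blurred = ndimage.gaussian_filter(image, sigma=float(width))
        interface = ndimage.binary_dilation(mask == a, iterations=max(1, int(width))) & (
            ndimage.binary_dilation(mask == b, iterations=max(1, int(width)))
        )
        image[interface] = blurred[interface]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    voxvol = spec.voxel_volume_mm3
    true_volumes = {
        int(k): float(np.count_nonzero(mask == k) * voxvol / 1000.0) for k in STRUCTURES
    }
    return PhantomSample(
        image=ImageGrid(image, spacing),
        mask=LabelMask(mask, spacing),
        true_volumes_ml=true_volumes,
        spec=spec,
    )


def _check_shell(mask, ndim):
    """Every LV boundary voxel's outward neighbourhood must hit LVM first."""
    struct = ndimage.generate_binary_structure(ndim, 1)
    lv = mask == LV
    ring = ndimage.binary_dilation(lv, structure=struct) & ~lv
    outside_shell = ring & (mask != LVM) & (mask != LV)
    if np.any(outside_shell):
        raise PhantomSizingError(LVM, "myocardial shell does not enclose the LV pool")


def generate_dataset(spec: PhantomSpec, n: int, seed: int | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms with independently jittered geometry.

    Child seeds are derived deterministically from ``seed`` (default:
    ``spec.seed``), so the whole dataset is reproducible.  Jitter draws whose
    sampled volumes cannot be packed into the grid are rejected and replaced
    by further deterministic child seeds (the largest literature volume
    ranges occasionally exceed the grid under unlucky jitter); a persistent
    failure to place any phantom raises.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base = spec.seed if seed is None else int(seed)
    max_attempts = 4 * n + 16
    child_seeds = np.random.SeedSequence(base).generate_state(max_attempts) % (2**31)
    out = []
    last_error: PhantomSizingError | None = None
    for s in child_seeds:
        if len(out) == n:
            break
        try:
            out.append(generate_phantom(dataclasses.replace(spec, seed=int(s))))
        except PhantomSizingError as err:
            last_error = err
    if len(out) < n:
        raise PhantomSizingError(
            last_error.structure if last_error else LV,
            f"only {len(out)}/{n} phantoms feasible in {max_attempts} attempts",
        )
    return out
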