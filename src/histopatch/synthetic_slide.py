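"""Procedural pseudo-histology generator.

Emulates the structure of an H&E cohort at desk scale: per "patient" a
tumor slide, a normal slide and a tumor-normal interface slide, each with a
congruent binary cancer mask, per-slide global stain variation and optional
out-of-focus artifact regions.  Normal tissue is rendered in an eosin-pink
family with sparse large nuclei; cancer in a hematoxylin-purple family with
dense small nuclei; background is near-white.  Textures are procedural
(filtered noise plus stamped elliptical nuclei) so generation is fast and
bit-reproducible from the seed.

This generator trades realism for controllability: classes are separable by
design (a configurable hue margin), which is what makes the downstream
pipeline testable end to end without clinical data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .augment import hsv_to_rgb, rgb_to_hsv

ROLES = ("tumor", "normal", "interface")
SPLITS = ("train", "validation", "test")

#: Minimum slide side: hosts a 101-pixel patch grid at stride 50 (3 origins).
MIN_SLIDE_SIDE = 202

# Base colors (RGB in [0,1]) of the two tissue families and their nuclei.
_NORMAL_BASE = (0.91, 0.62, 0.73)  # eosin pink
_NORMAL_NUCLEUS = (0.48, 0.28, 0.55)
_CANCER_BASE = (0.62, 0.42, 0.75)  # hematoxylin purple
_CANCER_NUCLEUS = (0.25, 0.12, 0.42)
_BACKGROUND = 0.96


@dataclass(frozen=True)
class SlideSpec:
    """Parameters for one generated slide."""

    height: int
    width: int
    role: str
    cancer_fraction: float = 0.0
    stain_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    artifact_fraction: float = 0.0
    seed: int = 0
    tissue_fraction: float = 0.8

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not in {ROLES}")
        if self.height < MIN_SLIDE_SIDE or self.width < MIN_SLIDE_SIDE:
            raise ValueError(
                f"slide {self.height}x{self.width} smaller than "
                f"{MIN_SLIDE_SIDE}x{MIN_SLIDE_SIDE}: cannot host a stride-50 patch grid"
            )
        for name in ("cancer_fraction", "artifact_fraction", "tissue_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.role == "normal" and self.cancer_fraction != 0.0:
            raise ValueError("normal slides must have cancer_fraction = 0")
        if self.role == "tumor" and self.cancer_fraction < 0.8:
            raise ValueError("tumor slides must have cancer_fraction >= 0.8")


@dataclass
class ManifestRow:
    patient_id: str
    slide: str
    mask: str
    role: str
    split: str


@dataclass
class CohortManifest:
    """Rows assigning slides/masks to patients, roles and patient-disjoint splits."""

    rows: list[ManifestRow] = field(default_factory=list)
    root: Path | None = None

    def subset(self, split: str) -> "CohortManifest":
        return CohortManifest([r for r in self.rows if r.split == split], self.root)

    def patients(self) -> list[str]:
        return sorted({r.patient_id for r in self.rows})

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for r in self.rows:
            if r.split not in SPLITS:
                raise ValueError(f"unknown split {r.split!r}")
            if seen.setdefault(r.patient_id, r.split) != r.split:
                raise ValueError(f"patient {r.patient_id} appears in two splits")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "slide", "mask", "role", "split"])
            for r in self.rows:
                w.writerow([r.patient_id, r.slide, r.mask, r.role, r.split])

    @classmethod
    def read_csv(cls, path) -> "CohortManifest":
        path = Path(path)
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    ManifestRow(
                        rec["patient_id"], rec["slide"], rec["mask"], rec["role"], rec["split"]
                    )
                )
        m = cls(rows, root=path.parent)
        m.validate()
        return m


# ----------------------------------------------------------------- internals

def _smooth_noise(rng, shape, sigma):
    # Large-sigma fields are generated on a decimated grid and upsampled:
    # identical character, far cheaper than filtering at full resolution.
    k = max(1, int(sigma // 8))
    if k > 1:
        from skimage.transform import resize

        coarse = gaussian_filter(
            rng.standard_normal((shape[0] // k + 1, shape[1] // k + 1)), sigma / k
        )
        f = resize(coarse, shape, order=1, mode="edge", anti_aliasing=False)
    else:
        f = gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _region_from_field(fieldvals, inside, fraction):
    """Boolean region covering ``fraction`` of ``inside``, by field quantile."""
    if fraction <= 0.0:
        return np.zeros_like(inside)
    if fraction >= 1.0:
        return inside.copy()
    vals = fieldvals[inside]
    thr = np.quantile(vals, 1.0 - fraction)
    return inside & (fieldvals > thr)


def _stamp_nuclei(canvas, region, rng, *, radius, density, color, aspect_jitter=0.5):
    """Stamp elliptical nuclei into ``canvas`` at random positions in ``region``."""
    h, w, _ = canvas.shape
    idx = np.flatnonzero(region)
    if idx.size == 0:
        return
    n = int(density * idx.size)
    if n == 0:
        return
    centers = rng.choice(idx, size=n, replace=True)
    cy, cx = np.divmod(centers, w)
    # One precomputed footprint per nucleus shape; a few shapes suffice.
    ry = np.maximum(1, np.round(radius * (1 + aspect_jitter * rng.uniform(-1, 1, n)))).astype(int)
    rx = np.maximum(1, np.round(radius * (1 + aspect_jitter * rng.uniform(-1, 1, n)))).astype(int)
    color = np.asarray(color, dtype=np.float32)
    for shape_key in set(zip(ry.tolist(), rx.tolist())):
        a, b = shape_key
        sel = (ry == a) & (rx == b)
        dy, dx = np.mgrid[-a : a + 1, -b : b + 1]
        disk = (dy / a) ** 2 + (dx / b) ** 2 <= 1.0
        oy, ox = np.nonzero(disk)
        oy = oy - a
        ox = ox - b
        yy = cy[sel][:, None] + oy[None, :]
        xx = cx[sel][:, None] + ox[None, :]
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        flat = (yy[ok] * w + xx[ok]).ravel()
        flat = flat[region.ravel()[flat]]  # keep nuclei inside their tissue class
        canvas.reshape(-1, 3)[flat] = color


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one pseudo-histology slide and its binary cancer mask.

    Returns ``(slide, mask)`` with ``slide`` an (H, W, 3) float32 RGB image
    in [0, 1] and ``mask`` an (H, W) uint8 array in {0, 1}, 1 exactly on
    cancer pixels.  Deterministic in ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    sigma = max(h, w) / 10.0

    # Tissue blob: smoothed noise biased toward the slide center.
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    tissue_field = _smooth_noise(rng, (h, w), sigma) + 2.0 * (1.0 - r2)
    thr = np.quantile(tissue_field, 1.0 - spec.tissue_fraction)
    tissue = tissue_field > thr

    # Cancer region inside the tissue; a directional gradient keeps the
    # interface slides' tumor-normal boundary connected.
    theta = rng.uniform(0, 2 * np.pi)
    grad = np.cos(theta) * (yy - h / 2) / h + np.sin(theta) * (xx - w / 2) / w
    cancer_field = _smooth_noise(rng, (h, w), sigma) + 12.0 * grad
    cancer = _region_from_field(cancer_field, tissue, spec.cancer_fraction)
    normal = tissue & ~cancer

    # Base coloring + low-amplitude texture noise.
    slide = np.empty((h, w, 3), dtype=np.float32)
    slide[:] = _BACKGROUND + 0.03 * rng.standard_normal((h, w, 1)).astype(np.float32)
    tex = _smooth_noise(rng, (h, w), 2.0).astype(np.float32)
    for region, base in ((normal, _NORMAL_BASE), (cancer, _CANCER_BASE)):
        for c in range(3):
            slide[..., c][region] = base[c] + 0.04 * tex[region]

    # Nuclei: sparse/large in normal tissue, dense/small in cancer.
    _stamp_nuclei(slide, normal, rng, radius=5, density=0.0010, color=_NORMAL_NUCLEUS)
    _stamp_nuclei(slide, cancer, rng, radius=2, density=0.0120, color=_CANCER_NUCLEUS)

    slide = np.clip(slide, 0.0, 1.0)

    # Per-slide global stain shift, applied in HSV.
    dh, ds, dv = spec.stain_shift
    if (dh, ds, dv) != (0.0, 0.0, 0.0):
        hsv = rgb_to_hsv(slide)
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + ds), 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + dv), 0.0, 1.0)
        slide = hsv_to_rgb(hsv)

    # Optional out-of-focus artifact: Gaussian blur composited over a region.
    if spec.artifact_fraction > 0.0:
        afield = _smooth_noise(rng, (h, w), sigma / 2)
        aregion = _region_from_field(afield, np.ones((h, w), bool), spec.artifact_fraction)
        blurred = np.stack([gaussian_filter(slide[..., c], 4.0) for c in range(3)], axis=-1)
        slide = np.where(aregion[..., None], blurred, slide)

    return np.clip(slide, 0.0, 1.0).astype(np.float32), cancer.astype(np.uint8)


# -------------------------------------------------------------------- cohort

#: Default cancer fraction (of tissue area) per slide role.
ROLE_CANCER_FRACTION = {"tumor": 0.9, "normal": 0.0, "interface": 0.5}

#: Half-widths of the per-slide uniform stain-shift draw (hue, sat, value).
STAIN_SHIFT_RANGE = (0.02, 0.10, 0.05)


def _assign_splits(n_patients, split_fractions, rng):
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions {split_fractions} must sum to 1")
    n_nonzero = sum(1 for f in split_fractions if f > 0)
    if n_patients < n_nonzero:
        raise ValueError(
            f"{n_patients} patients cannot be split into {n_nonzero} disjoint non-empty groups"
        )
    # Largest-remainder apportionment, then at least one patient per
    # non-empty split, then randomized assignment.
    ideal = np.array(split_fractions) * n_patients
    counts = np.floor(ideal).astype(int)
    rema = ideal - counts
    while counts.sum() < n_patients:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    for i, f in enumerate(split_fractions):
        if f > 0 and counts[i] == 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            counts[i] += 1
    order = rng.permutation(n_patients)
    assignment = {}
    pos = 0
    for split, c in zip(SPLITS, counts):
        for k in order[pos : pos + c]:
            assignment[int(k)] = split
        pos += c
    return assignment


def generate_cohort(
    n_patients: int,
    dims: tuple[int, int],
    split_fractions: tuple[float, float, float],
    seed: int,
    out_dir,
    artifact_fraction: float = 0.0,
) -> CohortManifest:
    """Write a synthetic cohort (3 slides per patient) and its manifest.

    Each patient gets a tumor, a normal and an interface slide with an
    independently drawn global stain shift.  Splits are patient-disjoint,
    randomized with the cohort seed.  Files: RGB slide PNGs, {0,255} mask
    PNGs, and ``manifest.csv``.
    """
    from . import slide_io  # deferred: avoids import cycle at module load

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignment = _assign_splits(n_patients, split_fractions, rng)
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for role in ROLES:
            shift = tuple(rng.uniform(-a, a) for a in STAIN_SHIFT_RANGE)
            spec = SlideSpec(
                height=dims[0],
                width=dims[1],
                role=role,
                cancer_fraction=ROLE_CANCER_FRACTION[role],
                stain_shift=shift,
                artifact_fraction=artifact_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            slide, mask = generate_slide(spec)
            sname = f"{pid}_{role}.png"
            mname = f"{pid}_{role}_mask.png"
            slide_io.write_image(out_dir / sname, slide)
            slide_io.write_mask(out_dir / mname, mask)
            rows.append(ManifestRow(pid, sname, mname, role, assignment[p]))
    manifest = CohortManifest(rows, root=out_dir)
    manifest.validate()
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest


def hue_separation(slide: np.ndarray, mask: np.ndarray) -> float:
    """Circular distance between mean hue of cancer and normal tissue pixels.

    Diagnostic for the generator's class-separability contract; returns 0.0
    if either class is absent.
    """
    hsv = rgb_to_hsv(slide)
    tissue = hsv[..., 1] >= 0.05
    cancer = (mask > 0) & tissue
    normal = (mask == 0) & tissue
    if cancer.sum() == 0 or normal.sum() == 0:
        return 0.0

    def circ_mean(h):
        ang = 2 * np.pi * h
        return np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) % 1.0

    d = abs(circ_mean(hsv[..., 0][cancer]) - circ_mean(hsv[..., 0][normal]))
    return float(min(d, 1.0 - d))
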