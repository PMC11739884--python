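"""Synthetic labeled voxel phantoms of vertebra-disc stacks.

The phantom emulates what an automated spine MRI segmentation produces: a
3D integer label map at ~1 mm in-plane resolution with a much coarser slice
spacing (2.5-3.5 mm), in which each vertebra and each intervertebral disc
(IVD) carries one label.  Vertebral bodies are superellipse-cross-section
cylinders (optionally with a posterior lobe standing in for the vertebral
arch), discs are flatter blobs between consecutive bodies.  The coarse
slice spacing produces the stair-step surface artifacts the downstream
smoothing stages exist to handle.

Label convention: vertebrae carry labels in 4..25 (one per spinal level);
the disc between vertebrae ``v`` and ``v+1`` carries label ``100 + v`` and
the sidecar name ``ivd_<v>_<v+1>``.

Defects observed in real segmentation masks can be injected: sub-threshold
voxel islands, a second disconnected volume, or an internal cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import gamma

from .volume_io import LabelVolume

VERT_LABEL_MIN = 4
VERT_LABEL_MAX = 25
IVD_LABEL_OFFSET = 100

DEFECT_KINDS = ("small_component", "disconnected_volume", "internal_hole")


class InvalidSpecError(ValueError):
    """Raised for geometrically impossible or ill-typed phantom requests."""


class DefectError(ValueError):
    """Raised for unknown defect kinds or absent labels."""


def ivd_label(lower_vertebra: int) -> int:
    """Label of the disc between vertebra ``lower_vertebra`` and the next."""
    return IVD_LABEL_OFFSET + lower_vertebra


def is_ivd_label(label: int) -> bool:
    return label >= IVD_LABEL_OFFSET


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vertebra-disc stack.

    ``jitter`` perturbs per-level radii, centres and cross-section exponent
    by up to the given relative amplitude (reproducibly from ``seed``), so a
    cohort of specs differing only in seed emulates anatomical variation.
    Defaults describe a small (cervical-scale) stack: 10 mm body semi-axis,
    16 mm body height, 6 mm disc height, 1x1x3 mm voxels.
    """

    n_levels: int = 3
    body_radius_mm: float = 10.0
    body_height_mm: float = 16.0
    disc_height_mm: float = 6.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    jitter: float = 0.1
    seed: int = 0
    base_label: int = 10
    superellipse_exponent: float = 2.5
    posterior_lobe: bool = False
    defects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise InvalidSpecError("n_levels must be >= 1")
        for name in ("body_radius_mm", "body_height_mm"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.n_levels > 1 and self.disc_height_mm <= 0:
            raise InvalidSpecError("disc_height_mm must be positive for multi-level stacks")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError(f"non-positive spacing: {self.spacing_mm}")
        if not 0.0 <= self.jitter <= 0.3:
            raise InvalidSpecError("jitter must lie in [0, 0.3]")
        if not VERT_LABEL_MIN <= self.base_label <= VERT_LABEL_MAX:
            raise InvalidSpecError(
                f"base_label must lie in {VERT_LABEL_MIN}..{VERT_LABEL_MAX}")
        if self.base_label + self.n_levels - 1 > VERT_LABEL_MAX:
            raise InvalidSpecError("vertebra labels would exceed the 4..25 range")

    @property
    def vertebra_labels(self) -> list[int]:
        return [self.base_label + i for i in range(self.n_levels)]

    @property
    def ivd_labels(self) -> list[int]:
        return [ivd_label(v) for v in self.vertebra_labels[:-1]]


def superellipse_area(a: float, b: float, p: float) -> float:
    """Area enclosed by |x/a|^p + |y/b|^p = 1 (closed form)."""
    return 4.0 * a * b * gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p)


def _level_shapes(spec: PhantomSpec) -> list[dict]:
    """Per-body geometric parameters, jittered reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    a0 = spec.body_radius_mm
    b0 = 0.8 * spec.body_radius_mm
    shapes = []
    z = 0.0
    for i, v in enumerate(spec.vertebra_labels):
        u = rng.uniform(-1.0, 1.0, size=6)
        shapes.append({
            "label": v,
            "kind": "vertebra",
            "a": a0 * (1.0 + spec.jitter * u[0]),
            "b": b0 * (1.0 + spec.jitter * u[1]),
            "cx": a0 * spec.jitter * 0.5 * u[2],
            "cy": b0 * spec.jitter * 0.5 * u[3],
            "p": spec.superellipse_exponent * (1.0 + 0.5 * spec.jitter * u[4]),
            "z_lo": z,
            "z_hi": z + spec.body_height_mm,
        })
        z += spec.body_height_mm
        if i < spec.n_levels - 1:
            w = rng.uniform(-1.0, 1.0, size=4)
            shapes.append({
                "label": ivd_label(v),
                "kind": "ivd",
                "a": 0.9 * a0 * (1.0 + spec.jitter * w[0]),
                "b": 0.9 * b0 * (1.0 + spec.jitter * w[1]),
                "cx": a0 * spec.jitter * 0.5 * w[2],
                "cy": b0 * spec.jitter * 0.5 * w[3],
                "p": spec.superellipse_exponent,
                "z_lo": z,
                "z_hi": z + spec.disc_height_mm,
            })
            z += spec.disc_height_mm
    return shapes


def generate_phantom(spec: PhantomSpec) -> LabelVolume:
    """Voxelize the stack described by ``spec`` into a label volume.

    Bodies tile the z axis without gaps (vertebra, disc, vertebra, ...), so
    adjacent surfaces extracted later are one voxel layer apart — the
    shared-interface situation of real endplate contact.  Raises
    :class:`InvalidSpecError` if a body would receive no voxel slice at the
    requested spacing.
    """
    shapes = _level_shapes(spec)
    sx, sy, sz = spec.spacing_mm
    max_a = max(s["a"] + abs(s["cx"]) for s in shapes)
    max_b = max(s["b"] + abs(s["cy"]) for s in shapes)
    lobe_extra = 1.2 * 0.8 * spec.body_radius_mm if spec.posterior_lobe else 0.0
    margin = 3.0
    nx = int(np.ceil(2 * (max_a + margin) / sx))
    ny = int(np.ceil((2 * max_b + lobe_extra + 2 * margin) / sy))
    z_total = shapes[-1]["z_hi"]
    nz = int(np.ceil((z_total + 2 * margin) / sz))

    # world coordinates of voxel centres; stack centred in x/y (shifted in y
    # when a posterior lobe extends the section), starting near z = 0
    origin = np.array([
        -(nx - 1) / 2.0 * sx,
        -(ny - 1) / 2.0 * sy + lobe_extra / 2.0,
        -margin,
    ])
    x = origin[0] + np.arange(nx) * sx
    y = origin[1] + np.arange(ny) * sy
    z = origin[2] + np.arange(nz) * sz

    grid = np.zeros((nx, ny, nz), dtype=np.int32)
    names: dict[int, str] = {}
    X = x[:, None]
    Y = y[None, :]
    for s in shapes:
        zmask = (z >= s["z_lo"]) & (z < s["z_hi"])
        if not zmask.any():
            raise InvalidSpecError(
                f"body {s['label']} receives no voxel slice at spacing {spec.spacing_mm}")
        inside2d = (np.abs((X - s["cx"]) / s["a"]) ** s["p"]
                    + np.abs((Y - s["cy"]) / s["b"]) ** s["p"]) <= 1.0
        if spec.posterior_lobe and s["kind"] == "vertebra":
            la, lb = 0.45 * s["a"], 0.6 * s["b"]
            lcy = s["cy"] - s["b"] - 0.7 * lb
            lobe = (((X - s["cx"]) / la) ** 2 + ((Y - lcy) / lb) ** 2) <= 1.0
            inside2d = inside2d | lobe
        body = inside2d[:, :, None] & zmask[None, None, :]
        if (grid[body] != 0).any():
            raise InvalidSpecError(f"body {s['label']} overlaps a previous body")
        grid[body] = s["label"]
        if s["kind"] == "vertebra":
            names[s["label"]] = f"vert_{s['label']}"
        else:
            v = s["label"] - IVD_LABEL_OFFSET
            names[s["label"]] = f"ivd_{v}_{v + 1}"

    vol = LabelVolume.from_grid(grid, spec.spacing_mm, origin_mm=origin, names=names)
    for body, kind in spec.defects:
        vol = inject_defect(vol, body, kind)
    return vol


def _free_site(grid: np.ndarray, shape: tuple[int, int, int]) -> tuple[int, ...]:
    """Find a corner-ward all-background box with a 1-voxel clearance
    (sufficient separation under 26-connectivity)."""
    pad = 1
    full = tuple(s + 2 * pad for s in shape)
    for i in range(grid.shape[0] - full[0] + 1):
        for j in range(grid.shape[1] - full[1] + 1):
            for k in range(grid.shape[2] - full[2] + 1):
                box = grid[i:i + full[0], j:j + full[1], k:k + full[2]]
                if not box.any():
                    return (i + pad, j + pad, k + pad)
    raise DefectError("no free space to place defect island")


def inject_defect(vol: LabelVolume, body: int, kind: str) -> LabelVolume:
    """Inject a segmentation defect for label ``body``; other labels untouched.

    - ``small_component``: a 3-voxel island disjoint from the main blob
      (below the 4-linked-voxel cleanup threshold, so cleanup removes it).
    - ``disconnected_volume``: a second 3x3x3 component, well above the
      threshold, so the label genuinely has two volumes.
    - ``internal_hole``: a small cavity carved strictly inside the body,
      which surfaces later as a nested mesh component.
    """
    if kind not in DEFECT_KINDS:
        raise DefectError(f"unknown defect kind: {kind!r}")
    mask = vol.grid == body
    if not mask.any():
        raise DefectError(f"label {body} absent from volume")
    out = vol.copy()
    if kind == "small_component":
        i, j, k = _free_site(vol.grid, (3, 1, 1))
        out.grid[i:i + 3, j, k] = body
    elif kind == "disconnected_volume":
        i, j, k = _free_site(vol.grid, (3, 3, 3))
        out.grid[i:i + 3, j:j + 3, k:k + 3] = body
    else:  # internal_hole
        interior = ndimage.binary_erosion(mask, iterations=2)
        if not interior.any():
            raise DefectError(f"label {body} too thin to carve an internal hole")
        idx = np.argwhere(interior)
        centre = idx[len(idx) // 2]
        i, j, k = centre
        out.grid[i:i + 2, j:j + 2, k] = 0
    return out


def default_cohort(
    n_subjects: int = 30,
    n_levels: int = 3,
    jitter: float = 0.1,
    base_seed: int = 1,
    **spec_kwargs,
) -> list[PhantomSpec]:
    """Specs for a desk-scale cohort (default 30 subjects, 3 levels each).

    Alternating base labels emulate different spinal levels across subjects
    so the label-wise cohort statistics exercise several labels.
    """
    specs = []
    for i in range(n_subjects):
        base = VERT_LABEL_MIN + (i % 4) * 4  # 4, 8, 12, 16, 4, ...
        specs.append(PhantomSpec(
            n_levels=n_levels, jitter=jitter, seed=base_seed + i,
            base_label=base, **spec_kwargs))
    return specs
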