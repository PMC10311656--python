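"""Synthetic chromatin-fiber conformations and pseudo-atom point clouds.

Chromatin fragments are modelled as chains of nucleosomes — ~11 nm wide,
~6 nm tall disks of DNA wrapped around histone octamers — connected by
linker DNA whose contour length follows from the nucleosome repeat length
(NRL): linker_bp = NRL - 147, at 0.34 nm per base pair.  Conformations are
drawn from a seeded geometric rejection sampler (a self-avoiding chain with
an excluded-volume core and a tunable compaction bias) rather than from a
molecular-dynamics force field; at the ~3 nm voxel scale of STEM tomography
only the resulting mass distribution matters.

Two tetranucleosome folding motifs observed in chromatin-dense regions are
provided explicitly: the compact ``alpha_tetrahedron`` (four nucleosomes at
the vertices of a regular tetrahedron) and the planar, elongated
``beta_rhombus``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FiberConfig",
    "FiberConformation",
    "NucleosomeTemplate",
    "PointCloud",
    "FiberSamplingError",
    "make_template",
    "sample_fiber",
    "make_motif",
    "build_point_cloud",
    "generate_dataset",
]

#: nm of B-DNA contour per base pair
NM_PER_BP = 0.34
#: base pairs wrapped around the histone core
CORE_BP = 147
#: nucleosome disk radius / height in nm
DISK_RADIUS = 5.5
DISK_HEIGHT = 6.0
#: hard-core distance between nucleosome centers (half-height contact), nm
MIN_CENTER_DIST = 5.5
#: rejection-sampling retry cap per nucleosome
MAX_RETRIES = 1000

MotifKind = Literal["alpha_tetrahedron", "beta_rhombus"]


class FiberSamplingError(RuntimeError):
    """Raised when the excluded-volume rejection sampler exhausts its retries."""


@dataclass(frozen=True)
class FiberConfig:
    """Parameters of one sampled chromatin fragment.

    Parameters
    ----------
    n_nucleosomes : int
        Number of nucleosomes in the chain (>= 1).
    nrl_bp : int
        Nucleosome repeat length in base pairs (>= 147); the linker is
        ``nrl_bp - 147`` bp.
    compaction : float
        0 gives an extended zig-zag chain, 1 dense clustering near the
        excluded-volume contact distance.
    motif_spec : tuple of (index, kind)
        Optional tetranucleosome motifs inserted rigidly at the given chain
        indices (the motif occupies indices ``index .. index+3``).
    seed : int
        Fully determines the conformation.
    """

    n_nucleosomes: int = 8
    nrl_bp: int = 167
    compaction: float = 0.5
    motif_spec: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")
        if self.nrl_bp < CORE_BP:
            raise ValueError(f"nrl_bp must be >= {CORE_BP}")
        if not 0.0 <= self.compaction <= 1.0:
            raise ValueError("compaction must lie in [0, 1]")
        for idx, kind in self.motif_spec:
            if kind not in ("alpha_tetrahedron", "beta_rhombus"):
                raise ValueError(f"unknown motif kind {kind!r}")
            if idx < 0 or idx + 4 > self.n_nucleosomes:
                raise ValueError("motif does not fit in chain")

    @property
    def linker_bp(self) -> float:
        return float(self.nrl_bp - CORE_BP)


@dataclass
class FiberConformation:
    """Nucleosome centers (nm), disk orientations, and linker polylines."""

    centers: np.ndarray  # (n, 3) nm
    orientations: np.ndarray  # (n, 3, 3) rotation matrices
    linker_paths: list  # list of (k, 3) polylines, one per consecutive pair
    linker_bp: float = 20.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if len(self.orientations) != len(self.centers):
            raise ValueError("one orientation per nucleosome required")
        if len(self.linker_paths) != max(len(self.centers) - 1, 0):
            raise ValueError("need exactly n-1 linker paths")

    @property
    def n_nucleosomes(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class NucleosomeTemplate:
    """Pseudo-atom model of one nucleosome in its local (disk) frame.

    Atoms fill a cylinder of ``disk_radius`` × ``disk_height`` centered at
    the origin with the disk axis along local z.
    """

    atoms: np.ndarray  # (n_atoms, 3) nm, centered
    disk_radius: float = DISK_RADIUS
    disk_height: float = DISK_HEIGHT

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class PointCloud:
    """Pseudo-atom positions x_i (nm) with optional core/linker labels."""

    positions: np.ndarray  # (n, 3)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size and not np.all(np.isfinite(self.positions)):
            raise ValueError("point cloud contains non-finite coordinates")

    @property
    def n_points(self) -> int:
        return len(self.positions)


def make_template(
    n_atoms: int = 500,
    disk_radius: float = DISK_RADIUS,
    disk_height: float = DISK_HEIGHT,
    seed: int = 0,
) -> NucleosomeTemplate:
    """Sample a pseudo-atom nucleosome template uniformly inside its cylinder.

    Atoms are drawn as antipodal pairs so the template centroid is exactly
    the origin (an odd count adds one atom at the origin).
    """
    rng = np.random.default_rng(seed)
    n_half = n_atoms // 2
    # uniform in a cylinder: sqrt for radius, uniform angle and height
    r = disk_radius * np.sqrt(rng.random(n_half))
    theta = 2 * np.pi * rng.random(n_half)
    z = disk_height * (rng.random(n_half) - 0.5)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    atoms = np.concatenate([pts, -pts], axis=0)
    if n_atoms % 2:
        atoms = np.concatenate([atoms, np.zeros((1, 3))], axis=0)
    return NucleosomeTemplate(atoms=atoms, disk_radius=disk_radius, disk_height=disk_height)


# ---------------------------------------------------------------------------
# chain sampler
# ---------------------------------------------------------------------------

def _zigzag_direction(i: int, angle_deg: float = 50.0) -> np.ndarray:
    """Alternating direction of an ideal extended two-start zig-zag chain."""
    a = np.deg2rad(angle_deg)
    sign = 1.0 if i % 2 == 0 else -1.0
    return np.array([np.cos(a), sign * np.sin(a), 0.0])


def _linker_path(exit_pt: np.ndarray, entry_pt: np.ndarray, contour: float) -> np.ndarray:
    """Polyline from DNA exit to entry point, bowed out when slack exists."""
    d = float(np.linalg.norm(entry_pt - exit_pt))
    if contour <= d or d == 0.0:
        return np.stack([exit_pt, entry_pt])
    # two equal segments whose total length matches the linker contour
    h = np.sqrt((contour / 2.0) ** 2 - (d / 2.0) ** 2)
    axis = (entry_pt - exit_pt) / d
    # any unit vector perpendicular to the chord
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    mid = (exit_pt + entry_pt) / 2.0 + h * perp
    return np.stack([exit_pt, mid, entry_pt])


# DNA exit/entry points in the nucleosome local frame: on the disk rim,
# offset above/below the midplane where the wrapped superhelix ends.
_LOCAL_EXIT = np.array([DISK_RADIUS, 0.0, +1.0])
_LOCAL_ENTRY = np.array([DISK_RADIUS, 0.0, -1.0])


def _build_linkers(centers: np.ndarray, orientations: np.ndarray, linker_bp: float) -> list:
    contour = max(linker_bp * NM_PER_BP, 0.0)
    paths = []
    for i in range(len(centers) - 1):
        exit_pt = centers[i] + orientations[i] @ _LOCAL_EXIT
        entry_pt = centers[i + 1] + orientations[i + 1] @ _LOCAL_ENTRY
        paths.append(_linker_path(exit_pt, entry_pt, contour))
    return paths


_MOTIF_CENTERS: dict[str, np.ndarray] = {}


def _motif_centers(kind: str) -> np.ndarray:
    """Canonical nucleosome centers (nm) for the two tetranucleosome motifs."""
    if not _MOTIF_CENTERS:
        # regular tetrahedron, edge 7 nm (face-to-face nucleosome stacking scale)
        edge = 7.0
        tet = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        tet *= edge / np.sqrt(8.0)
        _MOTIF_CENTERS["alpha_tetrahedron"] = tet - tet.mean(axis=0)
        # planar rhombus, side 9 nm, short diagonal 7 nm (stacked pair across it)
        side, p = 9.0, 7.0
        q = np.sqrt(4 * side**2 - p**2)
        rho = np.array(
            [[-q / 2, 0, 0], [0, p / 2, 0], [q / 2, 0, 0], [0, -p / 2, 0]]
        )
        _MOTIF_CENTERS["beta_rhombus"] = rho - rho.mean(axis=0)
    return _MOTIF_CENTERS[kind].copy()


def make_motif(kind: MotifKind, nrl_bp: int = 167) -> FiberConformation:
    """Build one ideal tetranucleosome motif as a 4-nucleosome conformation.

    ``alpha_tetrahedron`` is compact (all six pairwise distances equal);
    ``beta_rhombus`` is planar and elongated with two distance scales.
    """
    if kind not in ("alpha_tetrahedron", "beta_rhombus"):
        raise ValueError(f"unknown motif kind {kind!r}")
    centers = _motif_centers(kind)
    orientations = np.broadcast_to(np.eye(3), (4, 3, 3)).copy()
    linker_bp = float(max(nrl_bp - CORE_BP, 0))
    return FiberConformation(
        centers=centers,
        orientations=orientations,
        linker_paths=_build_linkers(centers, orientations, linker_bp),
        linker_bp=linker_bp,
    )


def sample_fiber(config: FiberConfig) -> FiberConformation:
    """Draw one self-avoiding chromatin-fiber conformation.

    Consecutive centers sit between the 5.5 nm excluded-volume contact and
    the geometric maximum (linker contour + one disk diameter); the
    ``compaction`` parameter interpolates between the two and between
    zig-zag and isotropically random chain directions.

    Raises
    ------
    FiberSamplingError
        If a nucleosome cannot be placed without core overlap within the
        retry cap (long chains at compaction near 1).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nucleosomes
    contour = config.linker_bp * NM_PER_BP
    d_max = contour + 2 * DISK_RADIUS
    d_min = MIN_CENTER_DIST
    spacing = d_max - config.compaction * (d_max - d_min)

    motif_at = dict(config.motif_spec)
    centers = np.zeros((n, 3))
    orientations = np.empty((n, 3, 3))
    if 0 in motif_at:
        centers[0:4] = _motif_centers(motif_at[0])
        for j in range(4):
            orientations[j] = Rotation.random(rng=rng).as_matrix()
        i = 4
    else:
        orientations[0] = Rotation.random(rng=rng).as_matrix()
        i = 1
    while i < n:
        if i in motif_at:
            placed = _try_place_motif(centers[:i], motif_at[i], spacing, rng)
            if placed is None:
                raise FiberSamplingError(
                    "could not insert motif without violating the 5.5 nm "
                    "excluded-volume constraint"
                )
            centers[i : i + 4] = placed
            for j in range(4):
                orientations[i + j] = Rotation.random(rng=rng).as_matrix()
            i += 4
            continue
        prev = centers[i - 1]
        for attempt in range(MAX_RETRIES):
            zig = _zigzag_direction(i)
            rand = rng.normal(size=3)
            rand /= np.linalg.norm(rand)
            direction = (1.0 - config.compaction) * zig + config.compaction * rand
            nrm = np.linalg.norm(direction)
            if nrm < 1e-9:
                continue
            candidate = prev + spacing * direction / nrm
            if np.all(np.linalg.norm(centers[:i] - candidate, axis=1) >= MIN_CENTER_DIST - 1e-9):
                centers[i] = candidate
                orientations[i] = Rotation.random(rng=rng).as_matrix()
                break
        else:
            raise FiberSamplingError(
                f"failed to place nucleosome {i} after {MAX_RETRIES} retries: "
                "5.5 nm excluded-volume constraint unsatisfiable at "
                f"compaction={config.compaction}"
            )
        i += 1

    centers -= centers.mean(axis=0)  # center the fragment on the origin
    return FiberConformation(
        centers=centers,
        orientations=orientations,
        linker_paths=_build_linkers(centers, orientations, config.linker_bp),
        linker_bp=config.linker_bp,
    )


def _try_place_motif(
    existing: np.ndarray, kind: str, spacing: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Rigidly attach a 4-nucleosome motif after the last placed nucleosome."""
    base = _motif_centers(kind)
    prev = existing[-1]
    for _ in range(MAX_RETRIES):
        rot = Rotation.random(rng=rng).as_matrix()
        pts = base @ rot.T
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = prev + spacing * direction - pts[0]
        pts = pts + shift
        dists = np.linalg.norm(existing[None, :, :] - pts[:, None, :], axis=2)
        if dists.min() >= MIN_CENTER_DIST - 1e-9:
            return pts
    return None


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def _polyline_points(path: np.ndarray, n_pts: int) -> np.ndarray:
    """n_pts points evenly spaced in arc length along a polyline."""
    if n_pts <= 0:
        return np.empty((0, 3))
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total == 0.0:
        return np.repeat(path[:1], n_pts, axis=0)
    s = (np.arange(n_pts) + 0.5) / n_pts * total
    out = np.empty((n_pts, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, path[:, d])
    return out


def build_point_cloud(
    conf: FiberConformation,
    template: NucleosomeTemplate,
    linker_atoms_per_bp: float = 6.0,
) -> PointCloud:
    """Instantiate pseudo-atoms: one rigid template copy per nucleosome plus
    linker atoms spaced evenly along each linker polyline.

    The total count is exactly
    ``n_nucleosomes * template.n_atoms + sum(round(linker_bp * linker_atoms_per_bp))``.
    """
    if template.n_atoms == 0:
        raise ValueError("template must contain at least one atom")
    parts = []
    labels = []
    for c, R in zip(conf.centers, conf.orientations):
        parts.append(template.atoms @ R.T + c)
        labels.append(np.zeros(template.n_atoms, dtype=np.int8))
    n_linker = int(round(conf.linker_bp * linker_atoms_per_bp))
    for path in conf.linker_paths:
        pts = _polyline_points(np.asarray(path, dtype=float), n_linker)
        parts.append(pts)
        labels.append(np.ones(len(pts), dtype=np.int8))
    positions = np.concatenate(parts, axis=0) if parts else np.empty((0, 3))
    return PointCloud(positions=positions, labels=np.concatenate(labels))


# ---------------------------------------------------------------------------
# dataset sampling
# ---------------------------------------------------------------------------

def default_config_sampler(rng: np.random.Generator, seed: int) -> FiberConfig:
    """Study-condition distribution: 4-16 nucleosomes, NRL 150-200 bp,
    compaction uniform in [0, 1]."""
    return FiberConfig(
        n_nucleosomes=int(rng.integers(4, 17)),
        nrl_bp=int(rng.integers(150, 201)),
        compaction=float(rng.random()),
        seed=seed,
    )


def generate_dataset(
    n_images: int,
    config_sampler: Callable[[np.random.Generator, int], FiberConfig] | None = None,
    seed: int = 0,
) -> list[FiberConformation]:
    """Sample ``n_images`` independent seeded conformations."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    sampler = config_sampler or default_config_sampler
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_images).astype(np.int64)
    out = []
    for i in range(n_images):
        rng = np.random.default_rng(int(child_seeds[i]))
        cfg = sampler(rng, int(child_seeds[i]) % (2**31 - 1))
        out.append(sample_fiber(cfg))
    return out
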