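"""Ground-truth scenes of synaptic ectosomes deposited in synaptic footprints.

A scene is the fully labelled truth the rest of the pipeline is tested
against: circular cell footprints on a supported lipid bilayer, sub-100 nm
vesicles (synaptic ectosomes, SE) scattered inside each footprint, protein
clusters attached to vesicles, and bright fiducial beads.  All coordinates
are 2-D (TIRF plane), in nanometres, origin at the field corner.

Species follow the biology of the system:

* ``CD81`` (or WGA) — the membrane reference stain, a filled disk of
  uniform label density covering the whole vesicle;
* ``TCR`` — a compact receptor microcluster near the vesicle centre;
* partner species ``CD40L``, ``ICOS``, ``BST2`` — compact clusters that are
  either co-clustered with TCR (ICOS, BST2) or laterally offset by
  ~150 nm (CD40L), so that on an 84 nm vesicle the CD40L cluster sits at
  the rim, segregated from the central TCR cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEMBRANE_SPECIES = "CD81"
PARTNER_SPECIES = ("CD40L", "ICOS", "BST2")

#: classes a vesicle can belong to for a TCR-vs-partner pairing
POSITIVITY_CLASSES = ("TCR-only", "partner-only", "double-positive")


@dataclass(frozen=True)
class CellFootprint:
    """Circular synaptic footprint of one T cell on the bilayer."""

    id: int
    center_nm: tuple[float, float]
    radius_um: float


@dataclass(frozen=True)
class Vesicle:
    id: int
    cell_id: int
    center_nm: tuple[float, float]
    diameter_nm: float
    positivity: str  # one of POSITIVITY_CLASSES


@dataclass(frozen=True)
class ProteinCluster:
    id: int
    vesicle_id: int
    species: str
    center_nm: tuple[float, float]
    radius_nm: float
    n_molecules: int


@dataclass(frozen=True)
class SceneParams:
    """Tunable generator parameters; defaults emulate the study conditions.

    ``vesicles_per_cell_mean``/``sd`` follow the reported 36 +/- 3 SE per
    synapse; ``diameter_mean_nm``/``sd`` the reported 84 +/- 5 nm SE
    diameter; ``double_positive_fraction`` the reported fraction of SE
    positive for both TCR and the partner species (54.5% for CD40L).  The
    remainder is split equally between TCR-only and partner-only vesicles.
    """

    n_cells: int = 3
    cell_radius_um: float = 5.0
    vesicles_per_cell_mean: float = 36.0
    vesicles_per_cell_sd: float = 3.0
    diameter_mean_nm: float = 84.0
    diameter_sd_nm: float = 5.0
    partner_species: str = "CD40L"
    double_positive_fraction: float = 0.545
    # CD40L microclusters are laterally offset from the vesicle centre;
    # co-clustered partners (ICOS/BST2) and TCR sit near the centre.
    partner_offset_mean_nm: float = 150.0
    cluster_radius_nm: float = 20.0
    molecules_per_cluster: int = 30
    membrane_molecules_per_vesicle: int = 60
    n_fiducials: int = 10
    field_size_nm: tuple[float, float] | None = None  # auto from cells

    def validate(self) -> None:
        if self.diameter_mean_nm <= 0 or self.diameter_sd_nm < 0:
            raise ValueError("vesicle diameters must be positive")
        if not 0.0 <= self.double_positive_fraction <= 1.0:
            raise ValueError("double_positive_fraction must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need at least one cell footprint")
        if self.partner_species not in PARTNER_SPECIES:
            raise ValueError(f"unknown partner species {self.partner_species!r}")


@dataclass
class GroundTruthScene:
    params: SceneParams
    cells: list[CellFootprint]
    vesicles: list[Vesicle]
    protein_clusters: list[ProteinCluster]
    fiducials: np.ndarray  # (n, 2) nm
    field_size_nm: tuple[float, float]
    seed: int = 0
    molecule_positions: dict[int, np.ndarray] = field(default_factory=dict)
    # molecule_positions maps cluster id -> (n_molecules, 2) nm truth coords

    def clusters_of(self, vesicle_id: int) -> list[ProteinCluster]:
        return [c for c in self.protein_clusters if c.vesicle_id == vesicle_id]

    def molecules_by_species(self) -> dict[str, np.ndarray]:
        """All true molecule coordinates, pooled per species."""
        out: dict[str, list[np.ndarray]] = {}
        for c in self.protein_clusters:
            out.setdefault(c.species, []).append(self.molecule_positions[c.id])
        return {
            sp: np.concatenate(chunks) if chunks else np.empty((0, 2))
            for sp, chunks in out.items()
        }


def _sample_in_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _cluster_positions(
    rng: np.random.Generator,
    center: np.ndarray,
    cluster_radius: float,
    vesicle_center: np.ndarray,
    vesicle_radius: float,
    n: int,
) -> np.ndarray:
    """Gaussian cluster truncated to the vesicle disk."""
    sigma = cluster_radius / 2.0
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        draw = center + rng.normal(scale=sigma, size=(2 * (n - filled) + 8, 2))
        ok = np.linalg.norm(draw - vesicle_center, axis=1) <= vesicle_radius
        take = draw[ok][: n - filled]
        pts[filled : filled + len(take)] = take
        filled += len(take)
    return pts


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> GroundTruthScene:
    """Generate a fully labelled ground-truth scene.

    Deterministic: the same ``(params, seed)`` pair yields a bit-identical
    scene.  Raises ``ValueError`` on invalid parameters.
    """
    params = params or SceneParams()
    params.validate()
    rng = np.random.default_rng(seed)

    # cells on a jittered grid, spaced well apart
    pitch = 2.6 * params.cell_radius_um * 1000.0
    per_row = int(np.ceil(np.sqrt(params.n_cells)))
    cells = []
    for i in range(params.n_cells):
        gx, gy = i % per_row, i // per_row
        cx = (gx + 0.5) * pitch + rng.uniform(-200, 200)
        cy = (gy + 0.5) * pitch + rng.uniform(-200, 200)
        cells.append(CellFootprint(i, (cx, cy), params.cell_radius_um))
    n_rows = int(np.ceil(params.n_cells / per_row))
    field = params.field_size_nm or (per_row * pitch, n_rows * pitch)

    dp = params.double_positive_fraction
    class_probs = np.array([(1 - dp) / 2, (1 - dp) / 2, dp])

    vesicles: list[Vesicle] = []
    clusters: list[ProteinCluster] = []
    molecule_positions: dict[int, np.ndarray] = {}
    vid = 0
    cid = 0
    for cell in cells:
        n_ves = max(0, int(round(rng.normal(params.vesicles_per_cell_mean,
                                            params.vesicles_per_cell_sd))))
        if params.vesicles_per_cell_sd == 0:
            n_ves = int(round(params.vesicles_per_cell_mean))
        centers = np.asarray(cell.center_nm) + _sample_in_disk(
            rng, n_ves, cell.radius_um * 1000.0 * 0.9
        )
        for k in range(n_ves):
            d = rng.normal(params.diameter_mean_nm, params.diameter_sd_nm)
            d = max(d, 1.0)
            positivity = POSITIVITY_CLASSES[rng.choice(3, p=class_probs)]
            ves_center = centers[k]
            ves = Vesicle(vid, cell.id, tuple(ves_center), d, positivity)
            vesicles.append(ves)
            radius = d / 2.0

            # membrane reference label: uniform over the vesicle disk
            n_mem = params.membrane_molecules_per_vesicle
            mem_pts = ves_center + _sample_in_disk(rng, n_mem, radius)
            clusters.append(ProteinCluster(cid, vid, MEMBRANE_SPECIES,
                                           tuple(ves_center), radius, n_mem))
            molecule_positions[cid] = mem_pts
            cid += 1

            species = []
            if positivity in ("TCR-only", "double-positive"):
                species.append("TCR")
            if positivity in ("partner-only", "double-positive"):
                species.append(params.partner_species)
            for sp in species:
                if sp == "CD40L":
                    # offset cluster, truncated to stay on the vesicle:
                    # on vesicles smaller than the offset, sit at the rim
                    offset = min(rng.normal(params.partner_offset_mean_nm,
                                            params.partner_offset_mean_nm / 10.0),
                                 radius)
                    offset = max(offset, 0.0)
                else:
                    offset = abs(rng.normal(0.0, params.cluster_radius_nm / 2.0))
                    offset = min(offset, radius)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                c_center = ves_center + offset * np.array([np.cos(theta),
                                                           np.sin(theta)])
                n_mol = params.molecules_per_cluster
                pts = _cluster_positions(rng, c_center, params.cluster_radius_nm,
                                         ves_center, radius, n_mol)
                clusters.append(ProteinCluster(cid, vid, sp, tuple(c_center),
                                               params.cluster_radius_nm, n_mol))
                molecule_positions[cid] = pts
                cid += 1
            vid += 1

    fiducials = np.column_stack([
        rng.uniform(0.05 * field[0], 0.95 * field[0], size=params.n_fiducials),
        rng.uniform(0.05 * field[1], 0.95 * field[1], size=params.n_fiducials),
    ])

    return GroundTruthScene(
        params=params, cells=cells, vesicles=vesicles,
        protein_clusters=clusters, fiducials=fiducials,
        field_size_nm=field, seed=seed,
        molecule_positions=molecule_positions,
    )
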