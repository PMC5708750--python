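"""Synthetic tissues with known ground truth.

Generates packed, non-overlapping circular cells on a bounded field with
per-cell multi-marker intensities whose ordinal levels are known by
construction, controllable spatial clustering of molecular states, and a
configurable fraction of staining-QC failures.  Everything the metric
pipeline consumes — the TSV cell-table dialect, edge-pixel sets via
rasterization, pre-binned ordinal tables — can be produced from one seed,
byte-reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd

from .cell_table_io import CellTable, PathwayDefinition, PathwayNode, QC_PREFIX
from .pathway_states import MolecularStateAssignment, state_key
from .spatial_graph import D_CRITICAL, EdgePixelSet, NeighborGraph, neighbors_approximate

#: separation of the state-conditional intensity means, in units of their SD;
#: wide enough that study-wide percentile thresholding recovers the
#: generating level almost always (given balanced level marginals)
LEVEL_MEAN_STEP = 10.0
LEVEL_SD = 1.0


@dataclasses.dataclass
class SyntheticTissueSpec:
    """Parameters of one synthetic tissue.

    ``cluster_size`` controls the spatial state process: 1 draws each
    cell's state independently (iid multinomial); larger values grow
    contiguous same-state regions of roughly that many cells on the
    touching-cell graph.  ``state_probs`` defaults to equiprobable
    prototype states; ``n_prototypes`` prototype level-vectors are built
    balanced per marker so each ordinal level occupies about a third of the
    pooled intensities.
    """

    n_cells: int = 1300  # the average tumor-core yield (~10^6 cells / ~750 cores)
    radius_mean: float = 3.0  # µm, epithelial-cell scale
    radius_sd: float = 0.3
    packing: str = "hex"  # "hex" (jittered hexagonal grid) or "rsa"
    field_size: tuple[float, float] | None = None  # µm; required for "rsa"
    n_markers: int = 4
    n_states: int = 3
    n_prototypes: int = 6
    state_probs: tuple[float, ...] | None = None
    cluster_size: int = 1
    qc_failure_rate: float = 0.0
    jitter: float = 0.02  # hex-grid positional noise, fraction of the spacing
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTissueSpec":
        d = json.loads(text)
        if d.get("field_size") is not None:
            d["field_size"] = tuple(d["field_size"])
        if d.get("state_probs") is not None:
            d["state_probs"] = tuple(d["state_probs"])
        return cls(**d)


@dataclasses.dataclass
class SyntheticTissue:
    """A generated tissue plus its ground truth."""

    spec: SyntheticTissueSpec
    table: CellTable  # raw-intensity mode, ready for the standard pipeline
    true_levels: pd.DataFrame  # cell_id × panel key, the generating levels
    true_states: dict  # cell_id -> state key
    pathway: PathwayDefinition  # all markers, generation order

    def assignment(self) -> MolecularStateAssignment:
        """Ground-truth molecular state assignment (pre-QC-failure)."""
        vecs: dict[str, tuple[int, ...]] = {}
        lv = self.true_levels
        for cid, key in self.true_states.items():
            vecs.setdefault(key, tuple(int(v) for v in lv.loc[cid]))
        return MolecularStateAssignment(
            pathway=self.pathway.name,
            n_states=self.spec.n_states,
            states=dict(self.true_states),
            level_vectors=vecs,
        )

    def ordinal_table(self) -> pd.DataFrame:
        """Pre-binned ordinal mode: the generating levels as the ordinal table."""
        return self.true_levels.copy()


def _hex_positions(
    n_cells: int, spacing: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered hexagonal grid, touching spacing; row-major fill of a
    near-square block."""
    cols = max(1, int(math.ceil(math.sqrt(n_cells))))
    rows = int(math.ceil(n_cells / cols))
    pts = []
    dy = spacing * math.sqrt(3) / 2
    for r in range(rows):
        for c in range(cols):
            x = c * spacing + (spacing / 2 if r % 2 else 0.0)
            pts.append((x, r * dy))
    pts = np.asarray(pts[:n_cells], dtype=float)
    noise = rng.uniform(-jitter, jitter, size=pts.shape) * spacing
    return pts + noise


def _rsa_positions(
    n_cells: int,
    radii: np.ndarray,
    field: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Random sequential addition of non-overlapping disks."""
    w, h = field
    placed: list[tuple[float, float]] = []
    max_attempts = 200 * n_cells
    attempts = 0
    i = 0
    pts = np.empty((n_cells, 2))
    while i < n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"infeasible packing: placed {i}/{n_cells} disks in "
                f"{w:g}x{h:g} µm after {attempts} attempts"
            )
        attempts += 1
        x = rng.uniform(radii[i], w - radii[i])
        y = rng.uniform(radii[i], h - radii[i])
        ok = True
        for j, (px, py) in enumerate(placed):
            if (x - px) ** 2 + (y - py) ** 2 < (radii[i] + radii[j]) ** 2:
                ok = False
                break
        if ok:
            pts[i] = (x, y)
            placed.append((x, y))
            i += 1
    return pts


def _balanced_prototypes(
    n_prototypes: int, n_markers: int, n_states: int, rng: np.random.Generator
) -> np.ndarray:
    """Prototype level vectors with per-marker balanced level marginals."""
    proto = np.empty((n_prototypes, n_markers), dtype=int)
    base = np.resize(np.arange(n_states), n_prototypes)
    for m in range(n_markers):
        proto[:, m] = rng.permutation(base)
    return proto


def _clustered_prototype_draw(
    graph: NeighborGraph,
    n_cells: int,
    probs: np.ndarray,
    cluster_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded region growth: flood-fill prototype labels over the touching
    graph in patches of about ``cluster_size`` cells."""
    index = {c: i for i, c in enumerate(graph.cell_ids)}
    adj = [[] for _ in range(n_cells)]
    # fixed edge order: hash-seed-independent growth, reproducible across runs
    for a, b in sorted(graph.edges, key=lambda e: (index[e[0]], index[e[1]])):
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    label = np.full(n_cells, -1, dtype=int)
    for start in rng.permutation(n_cells):
        if label[start] >= 0:
            continue
        s = int(rng.choice(len(probs), p=probs))
        label[start] = s
        count = 1
        frontier = [int(start)]
        while frontier and count < cluster_size:
            nxt = []
            for cur in frontier:
                for nb in adj[cur]:
                    if label[nb] < 0 and count < cluster_size:
                        label[nb] = s
                        count += 1
                        nxt.append(nb)
            frontier = nxt
    return label


def marker_panel(n_markers: int) -> PathwayDefinition:
    """The synthetic marker panel as a pathway over all markers."""
    nodes = tuple(PathwayNode(f"M{i:02d}", "cell") for i in range(n_markers))
    return PathwayDefinition("synthetic_panel", nodes)


def generate_tissue(spec: SyntheticTissueSpec) -> SyntheticTissue:
    """Generate a synthetic tissue from a spec, reproducibly from its seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    radii = np.clip(
        rng.normal(spec.radius_mean, spec.radius_sd, size=n),
        0.3 * spec.radius_mean,
        None,
    )
    if spec.packing == "hex":
        # grid spacing 2·radius_mean minus the jitter allowance bounds the
        # disks so the packing stays overlap-free (tangent when jitter = 0
        # and radius_sd = 0)
        cap = spec.radius_mean * max(1.0 - 2.0 * math.sqrt(2.0) * spec.jitter, 0.5)
        radii = np.minimum(radii, cap)
        xy = _hex_positions(n, 2.0 * spec.radius_mean, spec.jitter, rng)
    elif spec.packing == "rsa":
        if spec.field_size is None:
            raise ValueError("rsa packing needs field_size")
        xy = _rsa_positions(n, radii, spec.field_size, rng)
    else:
        raise ValueError(f"unknown packing rule {spec.packing!r}")

    pathway = marker_panel(spec.n_markers)
    proto = _balanced_prototypes(spec.n_prototypes, spec.n_markers, spec.n_states, rng)
    if spec.state_probs is None:
        probs = np.full(spec.n_prototypes, 1.0 / spec.n_prototypes)
    else:
        probs = np.asarray(spec.state_probs, dtype=float)
        if len(probs) != spec.n_prototypes or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("state_probs must have n_prototypes entries summing to 1")

    cell_ids = [f"c{i:05d}" for i in range(n)]
    base = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": f"synthetic-{spec.seed}",
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_area": np.pi * radii**2,
        }
    )
    geometry = CellTable(f"synthetic-{spec.seed}", base)

    if spec.cluster_size <= 1:
        proto_idx = rng.choice(spec.n_prototypes, size=n, p=probs)
    else:
        graph = neighbors_approximate(geometry, D_CRITICAL)
        proto_idx = _clustered_prototype_draw(graph, n, probs, spec.cluster_size, rng)

    levels = proto[proto_idx]  # n × n_markers
    true_levels = pd.DataFrame(
        levels.astype(float), columns=pathway.keys, index=pd.Index(cell_ids, name="cell_id")
    )
    true_states = {
        cid: state_key(tuple(int(v) for v in row), spec.n_states)
        for cid, row in zip(cell_ids, levels)
    }

    intensities = (
        levels * LEVEL_MEAN_STEP
        + LEVEL_MEAN_STEP / 2
        + rng.normal(0.0, LEVEL_SD, size=levels.shape)
    )
    df = base.copy()
    df["nuclear_area"] = np.pi * (0.5 * radii) ** 2
    df["cytosol_area"] = df["cell_area"] - df["nuclear_area"]
    df["nuclei_count"] = 1
    df["is_epithelial"] = True
    qc = np.where(rng.uniform(size=n) < spec.qc_failure_rate, 0.5, 1.0)
    df[QC_PREFIX + "R1"] = qc
    for j, key in enumerate(pathway.keys):
        df[key] = np.clip(intensities[:, j], 0.0, None)

    table = CellTable(f"synthetic-{spec.seed}", df)
    return SyntheticTissue(spec, table, true_levels, true_states, pathway)


def rasterize(
    tissue: SyntheticTissue, pixel_size: float = 0.5, growth: float = 1.15
) -> tuple[np.ndarray, EdgePixelSet]:
    """Rasterize the tissue to a labeled segmentation mask and extract
    boundary pixels.

    Segmented epithelium is space-filling: adjoining cells meet along
    extended borders, not at single tangency points.  Each disk is
    therefore grown by ``growth`` and contested pixels go to the nearest
    center, producing abutting cell regions wherever disks are close —
    while isolated cells keep a surrounding gap.  Labels are 1-based cell
    indices; the returned edge-pixel set is keyed by cell_id.
    """
    df = tissue.table.cells
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    r = growth * np.sqrt(df["cell_area"].to_numpy(float) / np.pi)
    pad = r.max() + 2 * pixel_size
    x0, y0 = x.min() - pad, y.min() - pad
    w = int(np.ceil((x.max() + pad - x0) / pixel_size)) + 1
    h = int(np.ceil((y.max() + pad - y0) / pixel_size)) + 1
    mask = np.zeros((h, w), dtype=np.int32)
    best = np.full((h, w), np.inf)
    for i in range(len(df)):
        cx, cy, ri = (x[i] - x0) / pixel_size, (y[i] - y0) / pixel_size, r[i] / pixel_size
        rlo, rhi = int(np.floor(cy - ri)), int(np.ceil(cy + ri)) + 1
        clo, chi = int(np.floor(cx - ri)), int(np.ceil(cx + ri)) + 1
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        win = (d2 <= ri**2) & (d2 < best[rlo:rhi, clo:chi])
        mask[rr[win], cc[win]] = i + 1
        best[rlo:rhi, clo:chi] = np.where(win, d2, best[rlo:rhi, clo:chi])
    eps = EdgePixelSet.from_labeled_mask(mask, pixel_size)
    cell_ids = list(df["cell_id"])
    pixels = {cell_ids[lab - 1]: px for lab, px in eps.pixels.items()}
    return mask, EdgePixelSet(pixels, pixel_size)


# --- 19-cell worked example -------------------------------------------------

FIG2_FAMILY_CELL = "center"
FIG2_NEIGHBOR_CELL = "center"


@dataclasses.dataclass
class WorkedExample:
    """Hand-built 19-cell tissue with three molecular states whose social
    decomposition is 6 monomers, 4 dimers and 1 pentamer; the central cell
    has one same-state neighbor (its dimer partner) and a neighborhood of
    one/two/three cells in the three states."""

    table: CellTable
    states: dict[str, str]  # cell_id -> "A" | "B" | "C" state keys "0","1","2"
    family_cell: str
    neighbor_cell: str
    expected_social_sizes: dict[int, int]  # group size -> group count

    def assignment(self) -> MolecularStateAssignment:
        return MolecularStateAssignment(
            pathway="fig2",
            n_states=3,
            states=dict(self.states),
            level_vectors={"0": (0,), "1": (1,), "2": (2,)},
        )


def fig2_fixture() -> WorkedExample:
    """The packaged 19-cell worked example (unit radius disks; touching
    pairs placed 2.0–2.15 µm apart, non-touching pairs > 2.62 µm)."""
    A, B, C = "0", "1", "2"
    ring = {  # angle deg -> (id, state)
        0: ("ring_A1", A),
        60: ("ring_C3", C),
        120: ("ring_B1", B),
        170: ("ring_B2", B),
        235: ("ring_C1", C),
        295: ("ring_C2", C),
    }
    cells: list[tuple[str, float, float, str]] = [("center", 0.0, 0.0, A)]
    for ang, (cid, st) in ring.items():
        t = math.radians(ang)
        cells.append((cid, 2.0 * math.cos(t), 2.0 * math.sin(t), st))
    for i in range(5):  # pentamer chain
        cells.append((f"penta_{i}", 10.0 + 2.0 * i, 0.0, B))
    cells += [
        ("dimer_a0", 10.0, 6.0, A),
        ("dimer_a1", 12.0, 6.0, A),
        ("mono_0", 10.0, -6.0, A),
        ("mono_1", 14.0, -6.0, B),
        ("mono_2", 18.0, -6.0, C),
        ("mono_3", 16.0, 6.0, C),
        ("mono_4", 20.0, 6.0, A),
    ]
    df = pd.DataFrame(
        {
            "cell_id": [c[0] for c in cells],
            "sample_id": "fig2",
            "x": [c[1] for c in cells],
            "y": [c[2] for c in cells],
            "cell_area": math.pi,  # unit radius
            "STATE@cell": [float(c[3]) for c in cells],
        }
    )
    return WorkedExample(
        table=CellTable("fig2", df),
        states={c[0]: c[3] for c in cells},
        family_cell=FIG2_FAMILY_CELL,
        neighbor_cell=FIG2_NEIGHBOR_CELL,
        expected_social_sizes={1: 6, 2: 4, 5: 1},
    )
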