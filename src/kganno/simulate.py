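"""Synthetic generators for every input the pipeline consumes.

Everything here is a pure function of its spec and seed, emits the same
file formats the pipeline reads (OBO, GMT, MTX/CSV, markers CSV, truth CSV,
rulebook JSON), and records its planted ground truth in a manifest so tests
never peek at generator internals.

The expression simulator draws negative-binomial baseline counts (a standard
over-dispersed model for UMI data), plants co-expressed gene pairs through a
shared lognormal latent factor whose mixing weight is the target Pearson r,
and plants pathway activity by multiplying member-gene means in the target
cells.  It emulates the statistical signal the edge-inference stage looks
for; it does not model batch effects, dropout calibration or library-size
variation beyond the NB noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError

TOY_NAMESPACE = "TOY"


# ---------------------------------------------------------------------------
# ontologies
# ---------------------------------------------------------------------------

@dataclass
class ToyOntology:
    obo_text: str
    #: ground truth (child id, parent id) IS_A assertions
    edges: list[tuple[str, str]]
    #: term id -> name
    terms: dict[str, str]
    name_to_id: dict[str, str]
    root: str

    @property
    def lineages(self) -> list[str]:
        """Direct children of the root: the default lineage partition."""
        return sorted(c for c, p in self.edges if p == self.root)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.obo_text)
        return path


def _render_obo(
    terms: list[tuple[str, str]],
    edges: list[tuple[str, str]],
    synonyms: dict[str, list[str]] | None = None,
    obsolete: set[str] | None = None,
) -> str:
    names = dict(terms)
    parents: dict[str, list[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    blocks = ["format-version: 1.2", "ontology: toy", ""]
    for term_id, name in terms:
        blocks.append("[Term]")
        blocks.append(f"id: {term_id}")
        blocks.append(f"name: {name}")
        for syn in (synonyms or {}).get(term_id, []):
            blocks.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(parents.get(term_id, [])):
            blocks.append(f"is_a: {parent} ! {names[parent]}")
        if term_id in (obsolete or set()):
            blocks.append("is_obsolete: true")
        blocks.append("")
    return "\n".join(blocks)


def make_toy_ontology(depth: int, branching: int,
                      namespace: str = TOY_NAMESPACE) -> ToyOntology:
    """A complete rooted tree of cell-type terms, serialized as OBO.

    Term count follows the geometric series ``sum_{d=0..depth} branching^d``.
    Deterministic: the same (depth, branching) always yields identical bytes.
    """
    if depth < 1 or branching < 1:
        raise ParameterError("depth and branching must both be >= 1")
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{namespace}:{counter:07d}"

    root = next_id()
    terms: list[tuple[str, str]] = [(root, "cell")]
    edges: list[tuple[str, str]] = []
    frontier = [(root, "")]
    for level in range(1, depth + 1):
        new_frontier = []
        for parent_id, prefix in frontier:
            for b in range(1, branching + 1):
                label = f"{prefix}{b}" if not prefix else f"{prefix}.{b}"
                child = next_id()
                terms.append((child, f"type {label}"))
                edges.append((child, parent_id))
                new_frontier.append((child, label))
        frontier = new_frontier
    return ToyOntology(
        obo_text=_render_obo(terms, edges),
        edges=edges,
        terms=dict(terms),
        name_to_id={name: tid for tid, name in terms},
        root=root,
    )


def ontology_from_tree(
    tree: dict[str, str | None],
    synonyms: dict[str, list[str]] | None = None,
    obsolete: set[str] | None = None,
    namespace: str = TOY_NAMESPACE,
) -> ToyOntology:
    """Build a named toy ontology from a ``name -> parent name`` mapping.

    Ids are assigned in the mapping's insertion order, so the same tree
    always produces the same ids and bytes.
    """
    ids: dict[str, str] = {}
    for i, name in enumerate(tree, start=1):
        ids[name] = f"{namespace}:{i:07d}"
    terms = [(ids[n], n) for n in tree]
    edges = []
    roots = []
    for name, parent in tree.items():
        if parent is None:
            roots.append(ids[name])
        else:
            if parent not in ids:
                raise ParameterError(f"parent {parent!r} of {name!r} not in tree")
            edges.append((ids[name], ids[parent]))
    if len(roots) != 1:
        raise ParameterError(f"tree must have exactly one root, found {len(roots)}")
    syn_by_id = {ids[n]: s for n, s in (synonyms or {}).items()}
    obs_by_id = {ids[n] for n in (obsolete or set())}
    return ToyOntology(
        obo_text=_render_obo(terms, edges, syn_by_id, obs_by_id),
        edges=edges,
        terms=dict(terms),
        name_to_id=ids,
        root=roots[0],
    )


def random_isa_dag(
    n_terms: int, seed: int, extra_edge_prob: float = 0.15,
    namespace: str = TOY_NAMESPACE,
) -> ToyOntology:
    """A random rooted DAG: a random tree plus extra forward is_a edges.

    Every non-root term gets one tree parent among earlier terms; extra
    parents are added with the given probability, always pointing at an
    earlier term so acyclicity holds by construction.
    """
    if n_terms < 2:
        raise ParameterError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    ids = [f"{namespace}:{i:07d}" for i in range(1, n_terms + 1)]
    terms = [(ids[0], "cell")] + [(ids[i], f"type {i}") for i in range(1, n_terms)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_terms):
        parent = int(rng.integers(0, i))
        edges.append((ids[i], ids[parent]))
        if i >= 2 and rng.random() < extra_edge_prob:
            extra = int(rng.integers(0, i))
            if extra != parent:
                edges.append((ids[i], ids[extra]))
    return ToyOntology(
        obo_text=_render_obo(terms, edges),
        edges=edges,
        terms=dict(terms),
        name_to_id={name: tid for tid, name in terms},
        root=ids[0],
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    gene_x: str
    gene_y: str
    target_r: float
    context: str  # cell-type label the pair is correlated in


@dataclass(frozen=True)
class PlantedActivity:
    pathway_id: str
    members: tuple[str, ...]
    target_label: str
    boost: float = 8.0  # multiplicative mean shift in target cells


@dataclass
class ExpressionSpec:
    """Study conditions for one simulated dataset."""

    seed: int
    cell_types: list[str]
    n_cells_per_type: int = 60
    n_background_genes: int = 40
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_activities: list[PlantedActivity] = field(default_factory=list)
    base_mean: float = 20.0
    dispersion: float = 2.0  # NB shape; smaller = more over-dispersed
    pair_mean: float = 80.0  # mean count of planted-pair genes
    pair_sigma: float = 1.0  # lognormal latent sd for planted pairs


@dataclass
class SimulatedExpression:
    counts: np.ndarray  # cells × genes, integers
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str]
    manifest: dict


def simulate_expression(spec: ExpressionSpec) -> SimulatedExpression:
    """Generate counts with planted co-expression and pathway activity."""
    if len(spec.cell_types) < 2:
        raise ParameterError("need at least 2 cell types")
    if spec.n_cells_per_type < 3:
        raise ParameterError("need at least 3 cells per type")
    for pair in spec.planted_pairs:
        if pair.target_r > 0.99:
            raise ParameterError(f"target r {pair.target_r} > 0.99 is infeasible")
        if not 0 < pair.target_r:
            raise ParameterError("target r must be positive")

    rng = np.random.default_rng(spec.seed)
    genes: list[str] = [f"BG{i:04d}" for i in range(1, spec.n_background_genes + 1)]
    for act in spec.planted_activities:
        for g in act.members:
            if g not in genes:
                genes.append(g)
    for pair in spec.planted_pairs:
        for g in (pair.gene_x, pair.gene_y):
            if g not in genes:
                genes.append(g)
    gene_index = {g: i for i, g in enumerate(genes)}

    labels = [ct for ct in spec.cell_types for _ in range(spec.n_cells_per_type)]
    n_cells = len(labels)
    cell_ids = [f"cell{i:05d}" for i in range(1, n_cells + 1)]
    labels_arr = np.asarray(labels)

    # NB baseline: mean matrix, then counts ~ NB(shape, shape/(shape+mu))
    mu = np.full((n_cells, len(genes)), spec.base_mean)
    for act in spec.planted_activities:
        rows = np.flatnonzero(labels_arr == act.target_label)
        if rows.size == 0:
            raise ParameterError(
                f"activity target label {act.target_label!r} not among cell types"
            )
        cols = [gene_index[g] for g in act.members]
        mu[np.ix_(rows, cols)] *= act.boost
    shape = spec.dispersion
    counts = rng.negative_binomial(shape, shape / (shape + mu)).astype(np.int64)

    # planted pairs: shared lognormal latent within the context label with
    # Poisson observation noise.  Poisson noise and library-size
    # normalization attenuate the latent correlation slightly, so the latent
    # mixing weight is inflated by a fixed small-attenuation correction.
    for pair in spec.planted_pairs:
        rows = np.flatnonzero(labels_arr == pair.context)
        if rows.size == 0:
            raise ParameterError(f"pair context {pair.context!r} not among cell types")
        rho = min(0.99, pair.target_r / 0.97)
        z = rng.standard_normal(rows.size)
        for g in (pair.gene_x, pair.gene_y):
            eps = rng.standard_normal(rows.size)
            lat = spec.pair_sigma * (math.sqrt(rho) * z + math.sqrt(1 - rho) * eps)
            lam = spec.pair_mean * np.exp(lat - spec.pair_sigma**2 / 2)
            counts[rows, gene_index[g]] = rng.poisson(lam)

    manifest = {
        "seed": spec.seed,
        "cell_types": list(spec.cell_types),
        "n_cells_per_type": spec.n_cells_per_type,
        "planted_pairs": [
            {"gene_x": p.gene_x, "gene_y": p.gene_y, "target_r": p.target_r,
             "context": p.context}
            for p in spec.planted_pairs
        ],
        "planted_activities": [
            {"pathway_id": a.pathway_id, "members": list(a.members),
             "target_label": a.target_label, "boost": a.boost}
            for a in spec.planted_activities
        ],
    }
    return SimulatedExpression(counts, genes, cell_ids, labels, manifest)


def write_expression_csv(sim: SimulatedExpression, path: str | Path) -> Path:
    """Dense CSV: header = cell_id, cell_type, then gene columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id,cell_type," + ",".join(sim.gene_ids) + "\n")
        for i, cid in enumerate(sim.cell_ids):
            row = ",".join(str(int(v)) for v in sim.counts[i])
            fh.write(f"{cid},{sim.labels[i]},{row}\n")
    return path


def write_expression_mtx(sim: SimulatedExpression, outdir: str | Path) -> Path:
    """Matrix Market triple: matrix.mtx + genes.tsv + cells.tsv sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", csr_matrix(sim.counts))
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in sim.gene_ids))
    (outdir / "cells.tsv").write_text(
        "".join(f"{c}\t{l}\n" for c, l in zip(sim.cell_ids, sim.labels))
    )
    return outdir


# ---------------------------------------------------------------------------
# marker inputs and mixtures
# ---------------------------------------------------------------------------

def mix_markers(minority: list[str], majority: list[str],
                ratio: tuple[int, int] = (1, 9), n: int = 10) -> list[str]:
    """Interleave two marker lists at a stated minority:majority ratio."""
    if min(ratio) < 1:
        raise ParameterError("ratio parts must be >= 1")
    n_minor = max(1, round(n * ratio[0] / sum(ratio)))
    n_major = n - n_minor
    if n_minor > len(minority) or n_major > len(majority):
        raise ParameterError("not enough markers to honour the requested ratio")
    picked_minor = minority[:n_minor]
    picked_major = majority[:n_major]
    mixed = list(picked_major)
    step = max(1, len(mixed) // (n_minor + 1))
    for i, m in enumerate(picked_minor):
        mixed.insert(min(len(mixed), (i + 1) * step), m)
    return mixed


# ---------------------------------------------------------------------------
# composite demo world
# ---------------------------------------------------------------------------

#: lineage name -> (subtype name or None, sibling subtype or None)
_WORLD_TYPES: dict[str, tuple[str | None, str | None]] = {
    "T cell": ("CD4-positive T cell", "CD8-positive T cell"),
    "B cell": ("memory B cell", "naive B cell"),
    "natural killer cell": (None, None),
    "macrophage": ("microglial cell", "alveolar macrophage"),
    "monocyte": ("classical monocyte", "non-classical monocyte"),
    "fibroblast": (None, None),
    "endothelial cell": (None, None),
    "neutrophil": (None, None),
}

_WORLD_SYNONYMS = {
    "T cell": ["T lymphocyte"],
    "natural killer cell": ["NK cell"],
}


@dataclass
class DemoWorld:
    """A self-consistent miniature study: ontology, gene sets, expression,
    markers, truth labels and a mock rulebook whose evidence chains exist in
    the graph by construction."""

    seed: int
    ontology: ToyOntology
    gmt_text: str
    expression: SimulatedExpression
    clusters: list[dict]  # {"cluster_id", "markers", "truth_name", "truth_id", ...}
    rulebook: dict[str, list]
    markers_per_cluster: int = 10

    def write_inputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write every pipeline input file; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology": self.ontology.write(outdir / "ontology.obo"),
            "gene_sets": outdir / "pathways.gmt",
            "expression": write_expression_csv(self.expression, outdir / "expression.csv"),
            "markers": outdir / "markers.csv",
            "truth": outdir / "truth.csv",
            "rulebook": outdir / "rulebook.json",
        }
        paths["gene_sets"].write_text(self.gmt_text)
        n = self.markers_per_cluster
        with open(paths["markers"], "w") as fh:
            fh.write("cluster_id," + ",".join(f"marker_{i+1}" for i in range(n)) + "\n")
            for cl in self.clusters:
                fh.write(cl["cluster_id"] + "," + ",".join(cl["markers"]) + "\n")
        with open(paths["truth"], "w") as fh:
            fh.write("cluster_id,true_name,true_id\n")
            for cl in self.clusters:
                fh.write(f"{cl['cluster_id']},{cl['truth_name']},{cl['truth_id']}\n")
        paths["rulebook"].write_text(json.dumps(self.rulebook, indent=2, sort_keys=True))
        return paths


def _marker_symbol(lineage: str, i: int) -> str:
    stem = "".join(w[0] for w in lineage.upper().split())
    return f"{stem}{hash_free_suffix(lineage)}{i:02d}"


def hash_free_suffix(name: str) -> str:
    # short deterministic disambiguator without hashing: first 3 consonants
    consonants = [c for c in name.upper() if c.isalpha() and c not in "AEIOU "]
    return "".join(consonants[:3])


def demo_world(seed: int = 0, n_cells_per_type: int = 60,
               n_markers: int = 10, mixture_ratio: tuple[int, int] = (1, 9)) -> DemoWorld:
    """Build the canonical eight-cluster fixture world.

    Eight immune/stromal lineages hang under a common root; each cluster's
    truth is the lineage's planted subtype (or the lineage itself when it has
    none).  Each truth type owns a 12-gene pathway planted active in its
    cells, markers are drawn from those members, one marker pair per cluster
    is planted co-expressed in its own label, and the rulebook proposes the
    true lineage at rank 1 with two evidence-free distractors.  A ninth
    cluster mixes T- and B-cell markers at ``mixture_ratio``.
    """
    tree: dict[str, str | None] = {"cell": None}
    for lineage, (sub1, sub2) in _WORLD_TYPES.items():
        tree[lineage] = "cell"
        if sub1:
            tree[sub1] = lineage
        if sub2:
            tree[sub2] = lineage
    ontology = ontology_from_tree(tree, synonyms=_WORLD_SYNONYMS)
    name_to_id = ontology.name_to_id

    lineages = list(_WORLD_TYPES)
    truth_types = {
        lineage: (subs[0] or lineage) for lineage, subs in _WORLD_TYPES.items()
    }

    # one pathway of 12 dedicated genes per truth type, plus decoy pathways
    # on the sibling subtypes so stage 3 has competition
    pathway_members: dict[str, list[str]] = {}
    activities: list[PlantedActivity] = []
    pairs: list[PlantedPair] = []
    gmt_lines: list[str] = []
    for lineage in lineages:
        truth = truth_types[lineage]
        members = [_marker_symbol(lineage, i) for i in range(1, 13)]
        pw_id = f"PW_{hash_free_suffix(lineage)}_{lineages.index(lineage)+1}"
        pathway_members[truth] = members
        activities.append(
            PlantedActivity(pw_id, tuple(members), target_label=truth)
        )
        gmt_lines.append("\t".join([pw_id, f"{truth} program"] + members))
        pairs.append(PlantedPair(members[0], members[1], target_r=0.95, context=truth))

    spec = ExpressionSpec(
        seed=seed,
        cell_types=[truth_types[l] for l in lineages],
        n_cells_per_type=n_cells_per_type,
        planted_pairs=pairs,
        planted_activities=activities,
    )
    sim = simulate_expression(spec)

    clusters: list[dict] = []
    rulebook: dict[str, list] = {}
    from .annotate import marker_fingerprint  # local import avoids a cycle

    for idx, lineage in enumerate(lineages):
        truth = truth_types[lineage]
        markers = pathway_members[truth][:n_markers]
        cluster_id = f"c{idx+1:02d}"
        distractors = [
            lineages[(idx + 3) % len(lineages)],
            lineages[(idx + 5) % len(lineages)],
        ]
        proposals = [[lineage, name_to_id[lineage]]] + [
            [d, name_to_id[d]] for d in distractors
        ]
        rulebook[marker_fingerprint(markers)] = proposals
        clusters.append(
            {
                "cluster_id": cluster_id,
                "markers": markers,
                "lineage": lineage,
                "truth_name": truth,
                "truth_id": name_to_id[truth],
                "mixed": False,
            }
        )

    # mixture cluster: minority T-cell markers inside a B-cell majority
    t_markers = pathway_members[truth_types["T cell"]][:n_markers]
    b_markers = pathway_members[truth_types["B cell"]][:n_markers]
    mixed = mix_markers(t_markers, b_markers, ratio=mixture_ratio, n=n_markers)
    rulebook[marker_fingerprint(mixed)] = [
        ["B cell", name_to_id["B cell"]],
        ["T cell", name_to_id["T cell"]],
        ["natural killer cell", name_to_id["natural killer cell"]],
    ]
    clusters.append(
        {
            "cluster_id": "c_mix",
            "markers": mixed,
            "lineage": "B cell + T cell",
            "truth_name": truth_types["B cell"],
            "truth_id": name_to_id[truth_types["B cell"]],
            "mixed": True,
            "components": sorted([name_to_id["B cell"], name_to_id["T cell"]]),
        }
    )

    return DemoWorld(
        seed=seed,
        ontology=ontology,
        gmt_text="\n".join(gmt_lines) + "\n",
        expression=sim,
        clusters=clusters,
        rulebook=rulebook,
        markers_per_cluster=n_markers,
    )


def rulebook_with_truth_at_rank2(world: DemoWorld, cluster_id: str) -> dict[str, list]:
    """Variant rulebook demoting one cluster's true lineage to rank 2.

    Used to show that arbitration over several candidates recovers a truth
    the proposer did not rank first, which a single-candidate run cannot.
    """
    from .annotate import marker_fingerprint

    rulebook = {k: [list(p) for p in v] for k, v in world.rulebook.items()}
    cluster = next(c for c in world.clusters if c["cluster_id"] == cluster_id)
    fp = marker_fingerprint(cluster["markers"])
    entry = rulebook[fp]
    entry[0], entry[1] = entry[1], entry[0]  # demote the truth to rank 2
    return rulebook
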