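"""Synthetic fixtures with planted ground truth.

Everything downstream of raw mass spectrometry is testable against data
produced here: Yule species trees, binary presence/absence traits
simulated under independent or genuinely coevolving gain/loss chains,
replicate time-course peptide tables with planted cluster structure and
differential expression, plus small GO DAGs and operon tables.  Every
generator is a pure function of its seed.

The study generator emulates the design of a two-strain *Clostridium
thermocellum* time-course proteome: two strains followed over 3 and 4
growth timepoints respectively, four biological replicates each, with
a mean-variance trend on the log2 scale and left-censored missingness
at a per-sample detection limit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .coevolution import DEPENDENT_TRANSITIONS, PAIR_STATES
from .trees import SpeciesTree

__all__ = [
    "SimTraitConfig",
    "SimStudyConfig",
    "TruthSet",
    "sim_tree",
    "sim_ctmc_trait",
    "sim_trait_matrix",
    "sim_study",
    "sim_go",
    "sim_operons",
]


@dataclass
class SimTraitConfig:
    """Settings for presence/absence trait simulation on a species tree."""

    n_pairs_dependent: int = 2
    n_pairs_independent: int = 2
    rate_range: tuple[float, float] = (0.5, 3.0)
    dependence_strength: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rate_range
        if not (0 < lo <= hi):
            raise ValueError("rates must be positive and ordered")
        if self.dependence_strength < 1:
            raise ValueError("dependence_strength must be >= 1")


@dataclass
class SimStudyConfig:
    """Settings for the replicate time-course abundance study.

    ``variance_trend`` gives (intercept, slope) of log replicate variance
    against mean log2 abundance; the negative default slope reproduces
    the higher relative noise of low-abundance proteins.  ``n_invalid``
    proteins are emitted with a single peptide and a single PSM so they
    must fail the two-peptide/two-PSM validity rule downstream.
    """

    n_proteins: int = 400
    n_puf: int = 40
    strains: tuple[str, str] = ("strainA", "strainB")
    timepoints_per_strain: tuple[int, int] = (3, 4)
    replicates: int = 4
    n_clusters: int = 5
    de_fraction: float = 0.1
    de_effect_log2: float = 2.0
    cluster_amplitude: float = 1.0
    abundance_log2_mean: float = 25.0
    abundance_log2_sd: float = 2.5
    variance_trend: tuple[float, float] = (1.92, -0.15)
    variance_scatter_log: float = 0.4
    lod_quantile: float = 0.05
    peptides_per_protein: tuple[int, int] = (2, 8)
    n_invalid: int = 0
    length_range: tuple[int, int] = (100, 800)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0, 1]")
        if not (0 <= self.lod_quantile < 1):
            raise ValueError("lod_quantile must be in [0, 1)")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.n_invalid > self.n_proteins:
            raise ValueError("n_invalid cannot exceed n_proteins")


@dataclass
class TruthSet:
    """Planted ground truth accompanying a synthetic dataset."""

    true_de: dict[str, dict[str, float]] = field(default_factory=dict)
    true_clusters: dict[str, int] = field(default_factory=dict)
    true_dependent_pairs: set[tuple[str, str]] = field(default_factory=set)
    lod_threshold_per_sample: dict[str, float] = field(default_factory=dict)
    true_invalid: set[str] = field(default_factory=set)
    trait_attempts: dict[str, int] = field(default_factory=dict)
    invariant_traits: set[str] = field(default_factory=set)


def sim_tree(n_tips: int, seed: int = 0) -> SpeciesTree:
    """Yule (pure-birth) tree with unique tip labels and height 1.

    The return instant of a pure-birth simulation leaves the two newest
    tips with zero-length branches, so every tip branch is extended by
    the waiting time to the next birth before rescaling.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng)
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:02d}"
    return SpeciesTree.from_dendropy(tree).scale_height(1.0)


def dependent_rates(base: np.ndarray, strength: float) -> np.ndarray:
    """Eight-rate coevolving chain from four base rates.

    A trait's gain is multiplied by ``strength`` when its partner is
    present and its loss is multiplied by ``strength`` when the partner
    is absent, pushing the pair toward matching states; ``strength = 1``
    recovers the independent chain exactly.
    """
    x01, x10, y01, y10 = base
    # order of DEPENDENT_TRANSITIONS:
    # 00->01, 00->10, 01->00, 01->11, 10->00, 10->11, 11->01, 11->10
    return np.array([
        y01, x01,
        y10 * strength, x01 * strength,
        x10 * strength, y01 * strength,
        x10, y10,
    ])


def _pair_q(rates8: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(rates8, DEPENDENT_TRANSITIONS):
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def sim_ctmc_trait(tree: SpeciesTree, rates, model: str = "single",
                   seed: int = 0, root_prior=None):
    """Simulate a binary trait (or pair) down the tree by waiting times.

    ``rates`` is ``(q01, q10)`` for a single trait or eight rates (in
    :data:`DEPENDENT_TRANSITIONS` order) for a pair.  Returns a state
    vector aligned with ``tree.tip_labels``; for pairs the two binary
    columns are returned as an (n_tips, 2) array.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite and non-negative")
    if model == "single":
        if rates.shape != (2,):
            raise ValueError("single-trait simulation needs (q01, q10)")
        Q = np.array([[-rates[0], rates[0]], [rates[1], -rates[1]]])
    elif model == "dependent":
        if rates.shape != (8,):
            raise ValueError("pair simulation needs 8 rates")
        Q = _pair_q(rates)
    else:
        raise ValueError(f"unknown model {model!r}")
    n_states = Q.shape[0]
    prior = np.full(n_states, 1.0 / n_states) if root_prior is None else np.asarray(root_prior)
    rng = np.random.default_rng(seed)

    order = list(tree.tree.preorder_node_iter())
    node_state: dict[int, int] = {id(order[0]): int(rng.choice(n_states, p=prior))}
    tip_states: dict[str, int] = {}
    for node in order:
        if node.parent_node is None:
            s = node_state[id(node)]
        else:
            s = node_state[id(node.parent_node)]
            t_left = float(node.edge.length)
            while True:
                exit_rate = -Q[s, s]
                if exit_rate <= 0:
                    break
                wait = rng.exponential(1.0 / exit_rate)
                if wait > t_left:
                    break
                t_left -= wait
                probs = Q[s].clip(min=0.0)
                probs[s] = 0.0
                probs /= probs.sum()
                s = int(rng.choice(n_states, p=probs))
            node_state[id(node)] = s
        if node.is_leaf():
            tip_states[node.taxon.label] = s
    vec = np.array([tip_states[lab] for lab in tree.tip_labels])
    if model == "single":
        return vec
    xy = np.array(PAIR_STATES)[vec]  # rows (x, y)
    return xy


def sim_trait_matrix(tree: SpeciesTree, config: SimTraitConfig):
    """Trait matrix with planted coevolving pairs and independent pairs.

    Column names are synthetic orthogroup ids; the first member of each
    dependent pair is flagged as a PUF orthogroup.  Columns invariant
    across species are re-simulated up to 10 times (attempt counts kept
    in the truth set) and flagged if still invariant.
    """
    from .coevolution import TraitMatrix

    rng = np.random.default_rng(config.seed)
    columns: dict[str, np.ndarray] = {}
    truth = TruthSet()
    n_tips = tree.n_tips

    def variable(v):
        return 0 < v.sum() < n_tips

    def simulate_pair(dep: bool, name_x: str, name_y: str):
        for attempt in range(1, 11):
            base = rng.uniform(*config.rate_range, size=4)
            if dep:
                r8 = dependent_rates(base, config.dependence_strength)
                xy = sim_ctmc_trait(tree, r8, "dependent",
                                    seed=int(rng.integers(2**31)))
            else:
                x = sim_ctmc_trait(tree, base[:2], "single",
                                   seed=int(rng.integers(2**31)))
                y = sim_ctmc_trait(tree, base[2:], "single",
                                   seed=int(rng.integers(2**31)))
                xy = np.column_stack([x, y])
            truth.trait_attempts[name_x] = attempt
            truth.trait_attempts[name_y] = attempt
            if variable(xy[:, 0]) and variable(xy[:, 1]):
                return xy
        truth.invariant_traits.update(
            n for n, j in [(name_x, 0), (name_y, 1)] if not variable(xy[:, j]))
        return xy

    for i in range(config.n_pairs_dependent):
        nx, ny = f"OGdep{i:04d}a", f"OGdep{i:04d}b"
        xy = simulate_pair(True, nx, ny)
        columns[nx], columns[ny] = xy[:, 0], xy[:, 1]
        truth.true_dependent_pairs.add((nx, ny))
    for i in range(config.n_pairs_independent):
        nx, ny = f"OGind{i:04d}a", f"OGind{i:04d}b"
        xy = simulate_pair(False, nx, ny)
        columns[nx], columns[ny] = xy[:, 0], xy[:, 1]

    names = list(columns)
    matrix = np.column_stack([columns[n] for n in names])
    puf = {n for n in names if n.endswith("a")}
    return TraitMatrix(species=tree.tip_labels, orthogroups=names,
                       matrix=matrix, puf_orthogroups=puf), truth


def _phase_label(t: int, n_timepoints: int) -> str:
    """Growth-phase label for timepoint ``t`` (1-based).

    The first timepoint is early-log, the second mid-log and the last
    late-log; intermediate extra timepoints (a four-point series has
    one) are labelled ``other``.  Treating the second of four timepoints
    as mid-log mirrors PCA-based phase matching of a slower-growing
    strain's trajectory.
    """
    if t == 1:
        return "early"
    if t == 2:
        return "mid"
    if t == n_timepoints:
        return "late"
    return "other"


def sim_study(config: SimStudyConfig):
    """Two-strain replicate time-course with planted structure.

    Returns ``(peptides, samples, proteins, truth)``: a long-format
    peptide table, sample metadata, protein records and the truth set.
    Protein log2 abundance follows cluster-specific temporal profiles,
    strain effects of ``±de_effect_log2`` for the planted DE fraction,
    and Gaussian noise whose variance follows ``variance_trend``;
    peptide intensities below the per-sample ``lod_quantile`` are
    censored to missing (PSM count zero).
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    prot_ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1,
                           size=config.n_proteins)
    puf_ids = set(rng.choice(prot_ids, size=config.n_puf, replace=False))
    proteins = pd.DataFrame({
        "length_aa": lengths,
        "is_puf": [p in puf_ids for p in prot_ids],
        "annotation": ["hypothetical protein" if p in puf_ids else f"enzyme family {i % 23}"
                       for i, p in enumerate(prot_ids)],
    }, index=pd.Index(prot_ids, name="protein"))

    # samples
    rows = []
    for strain, n_tp in zip(config.strains, config.timepoints_per_strain):
        for t in range(1, n_tp + 1):
            for r in range(1, config.replicates + 1):
                rows.append({
                    "sample": f"{strain}_T{t}_R{r}", "strain": strain,
                    "timepoint": f"T{t}", "replicate": r,
                    "phase": _phase_label(t, n_tp),
                })
    samples = pd.DataFrame(rows).set_index("sample")

    # cluster temporal profiles on a shared phase-anchored pseudotime axis,
    # so matched phases carry identical cluster values in both strains and
    # the only strain differences are the planted DE effects
    phase_time = {"early": 0.0, "mid": 0.5, "other": 0.75, "late": 1.0}
    cluster_of = rng.integers(0, config.n_clusters, size=config.n_proteins)
    truth.true_clusters = dict(zip(prot_ids, map(int, cluster_of)))
    profiles: dict[tuple[int, str, str], float] = {}
    for c in range(config.n_clusters):
        coef = rng.normal(size=3)

        def shape(t):
            return coef[0] * np.sin(np.pi * t) + coef[1] * t + coef[2] * t ** 2

        grid = shape(np.linspace(0.0, 1.0, 9))
        center, spread = grid.mean(), max(grid.std(), 1e-9)
        for strain, n_tp in zip(config.strains, config.timepoints_per_strain):
            for t in range(1, n_tp + 1):
                ts = phase_time[_phase_label(t, n_tp)]
                val = (shape(ts) - center) / spread * config.cluster_amplitude
                profiles[(c, strain, f"T{t}")] = float(val)

    # planted DE proteins: strainB shifted at every phase, random sign
    n_de = int(round(config.de_fraction * config.n_proteins))
    de_ids = list(rng.choice(prot_ids, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    contrast_labels = ["early", "mid", "late"]
    for pid, sgn in zip(de_ids, signs):
        truth.true_de[pid] = {lab: float(sgn * config.de_effect_log2)
                              for lab in contrast_labels}

    base = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd,
                      size=config.n_proteins)
    icept, slope = config.variance_trend
    logvar = (icept + slope * base
              + rng.normal(0.0, config.variance_scatter_log, size=config.n_proteins))
    sds = np.sqrt(np.exp(logvar))

    invalid_ids = set(prot_ids[:config.n_invalid])
    truth.true_invalid = invalid_ids
    lo_pep, hi_pep = config.peptides_per_protein
    n_peps = rng.integers(lo_pep, hi_pep + 1, size=config.n_proteins)

    records = []
    strainB = config.strains[1]
    for i, pid in enumerate(prot_ids):
        n_pep = 1 if pid in invalid_ids else int(n_peps[i])
        weights = rng.dirichlet(np.ones(n_pep) * 5.0)
        de = truth.true_de.get(pid)
        for sid, meta in samples.iterrows():
            a = base[i] + profiles[(cluster_of[i], meta["strain"], meta["timepoint"])]
            if de is not None and meta["strain"] == strainB:
                a += next(iter(de.values()))
            a += rng.normal(0.0, sds[i])
            total = 2.0 ** a * lengths[i]
            for p in range(n_pep):
                psm = 1 if pid in invalid_ids else int(1 + rng.poisson(2.0))
                records.append((f"{pid}_pep{p}", pid, sid,
                                total * weights[p], psm))
    peptides = pd.DataFrame(records, columns=["peptide", "protein", "sample",
                                              "intensity", "psm_count"])

    # left-censor below the per-sample LOD quantile
    if config.lod_quantile > 0:
        for sid in samples.index:
            sel = peptides["sample"] == sid
            thr = float(peptides.loc[sel, "intensity"].quantile(config.lod_quantile))
            truth.lod_threshold_per_sample[sid] = thr
            below = sel & (peptides["intensity"] < thr)
            peptides.loc[below, "intensity"] = np.nan
            peptides.loc[below, "psm_count"] = 0
    else:
        truth.lod_threshold_per_sample = {sid: 0.0 for sid in samples.index}

    return peptides, samples, proteins, truth


def sim_go(n_terms: int, max_depth: int, genes: list[str], seed: int = 0):
    """Random GO-like DAG (tree plus extra edges) and gene annotations.

    Returns ``(dag, annotation_map)`` where the DAG is a
    ``networkx.MultiDiGraph`` with child->parent ``is_a`` edges (the
    in-memory form the OBO reader produces) and the annotation map sends
    each gene to 1-3 directly-annotated terms (unpropagated).
    """
    import networkx as nx

    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    dag = nx.MultiDiGraph()
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    depth = {ids[0]: 0}
    dag.add_node(ids[0], name="root", namespace="biological_process")
    for term in ids[1:]:
        eligible = [t for t in depth if depth[t] < max_depth]
        parent = eligible[int(rng.integers(len(eligible)))]
        depth[term] = depth[parent] + 1
        dag.add_node(term, name=f"term {term}", namespace="biological_process")
        dag.add_edge(term, parent, key="is_a")
    # a few extra is_a edges to make it a DAG rather than a tree
    for term in ids[1:]:
        if rng.random() < 0.15:
            shallower = [t for t in ids if depth[t] < depth[term]]
            extra = shallower[int(rng.integers(len(shallower)))]
            if not dag.has_edge(term, extra):
                dag.add_edge(term, extra, key="is_a")
    annotation = {g: set(rng.choice(ids, size=int(rng.integers(1, 4)),
                                    replace=False))
                  for g in genes}
    return dag, annotation


def sim_operons(genes: list[str], mean_size: float, seed: int = 0,
                coverage: float = 0.7) -> pd.DataFrame:
    """Partition a subset of genes into consecutive operon blocks.

    Returns a table with columns ``operon_id``, ``genes`` (ordered list)
    and ``annotations`` (one string per gene).  Roughly ``coverage`` of
    the gene list is assigned; block sizes are ``1 + Poisson(mean_size - 1)``.
    """
    if mean_size < 1:
        raise ValueError("mean_size must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = ["esterase/lipase", "glycoside hydrolase", "ABC transporter",
             "rubredoxin-type protein", "transcription factor",
             "hypothetical protein"]
    rows = []
    i = 0
    op = 0
    while i < len(genes):
        size = 1 + int(rng.poisson(max(mean_size - 1.0, 0.0)))
        block = genes[i:i + size]
        i += size
        if rng.random() < coverage:
            rows.append({
                "operon_id": f"op{op:04d}",
                "genes": list(block),
                "annotations": [vocab[int(rng.integers(len(vocab)))]
                                for _ in block],
            })
            op += 1
    return pd.DataFrame(rows, columns=["operon_id", "genes", "annotations"])
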