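"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a colorectal-cancer-like study design: bulk tumors
fall into three latent transcriptional programs (canonical, immune-activated,
stromal-activated), a ferroptosis gene list whose members partly overlap the
immune and stromal programs, survival driven by the stromal program, higher
mutation burden in the immune program group, and a single-cell compartment
where epithelial tumor cells carry the canonical or immune program while
stromal cells over-express the stromal ferroptosis genes.

Every block of output (expression / survival / mutations / single cell / ICB)
draws from its own RNG stream spawned from the master seed, so generating one
block never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    SingleCellMatrix,
)

__all__ = ["SimConfig", "SimTruth", "simulate_bulk_cohort",
           "simulate_single_cell_cohort", "simulate_icb_cohort"]

PROGRAMS = ("canonical", "immune", "stromal")
CELL_TYPES = ("epithelial", "T", "B", "myeloid", "stromal")

# RNG block indices; fixed so adding a block never shifts another stream.
_BLOCK = {"structure": 0, "expression": 1, "survival": 2, "mutation": 3,
          "single_cell": 4, "icb": 5}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the reference study design."""

    n_samples: int = 300
    n_genes: int = 2000
    # ferroptosis list: counts per role, proportioned like curated databases
    n_ferro_driver: int = 47
    n_ferro_suppressor: int = 40
    n_ferro_marker: int = 63
    # latent program sizes (genes per program)
    program_sizes: tuple[int, int, int] = (60, 60, 60)
    # ferroptosis genes embedded inside each program (symmetric overlap so
    # the three clusters are pairwise equidistant in ferroptosis-gene space)
    ferro_in_program: tuple[int, int, int] = (20, 20, 20)
    # cluster mixing proportions (canonical, immune, stromal)
    mixing: tuple[float, float, float] = (0.50, 0.35, 0.15)
    delta: float = 1.0          # program effect on log2 expression
    sigma: float = 0.5          # gene-level noise SD (log2 units)
    activity_sd: float = 0.0    # optional spread of the latent program activity
    baseline_range: tuple[float, float] = (2.0, 8.0)  # log2 baseline means
    # survival: exponential hazard lambda0 * exp(beta_cluster)
    lambda0: float = 1.0 / 1500.0        # events per day
    betas: tuple[float, float, float] = (0.0, 0.0, 0.8)
    censor_max_days: float = 6000.0      # uniform administrative censoring
    # clinical category skews per cluster
    stage_probs: tuple[tuple[float, ...], ...] = (
        (0.18, 0.40, 0.34, 0.08),   # canonical
        (0.23, 0.42, 0.31, 0.04),   # immune: early-stage enriched
        (0.05, 0.35, 0.44, 0.16),   # stromal: stage-IV enriched
    )
    msi_high_probs: tuple[float, float, float] = (0.12, 0.40, 0.08)
    # mutations
    n_mutation_genes: int = 120
    mutation_rate: float = 0.02
    immune_mutation_multiplier: float = 2.0
    # single cell
    n_cells: int = 2000
    cell_type_props: tuple[float, ...] = (0.40, 0.20, 0.10, 0.15, 0.15)
    n_type_markers: int = 40
    sc_marker_fold: float = 4.0
    sc_dispersion: float = 2.0
    sc_libsize_sd: float = 0.3
    # ICB cohort
    icb_n_samples: int = 150
    icb_gamma: float = 2.0      # logistic link of response on immune-stromal axis
    icb_response_log_hr: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ValueError("cluster mixing proportions must sum to 1")
        if abs(sum(self.cell_type_props) - 1.0) > 1e-9:
            raise ValueError("cell type proportions must sum to 1")
        if self.delta < 0 or self.sigma <= 0 or self.lambda0 <= 0:
            raise ValueError("delta >= 0, sigma > 0 and lambda0 > 0 required")
        structural = (sum(self.program_sizes)
                      + self.n_ferro_driver + self.n_ferro_suppressor
                      + self.n_ferro_marker
                      + self.n_mutation_genes
                      + len(CELL_TYPES) * self.n_type_markers)
        if structural > self.n_genes:
            raise ValueError(
                f"program/marker gene demands ({structural}) exceed n_genes "
                f"({self.n_genes})"
            )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth needed for recovery checks, no re-derivation required."""

    cluster_labels: pd.Series | None = None          # sample -> 1-based cluster
    cluster_names: dict[int, str] = field(default_factory=dict)
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    ferroptosis_roles: dict[str, str] = field(default_factory=dict)
    activity: pd.DataFrame | None = None             # samples x programs
    betas: dict[str, float] = field(default_factory=dict)
    cell_types: pd.Series | None = None
    cell_states: pd.Series | None = None             # epithelial program state
    type_markers: dict[str, list[str]] = field(default_factory=dict)
    response_prob: pd.Series | None = None

    def ferroptosis_program_genes(self, program: str) -> list[str]:
        ferro = set(self.ferroptosis_roles)
        return [g for g in self.program_genes[program] if g in ferro]


# ---------------------------------------------------------------------------
# shared structure
# ---------------------------------------------------------------------------


def _rng(config: SimConfig, block: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_BLOCK[block],))
    return np.random.default_rng(ss)


def _gene_structure(config: SimConfig) -> dict:
    """Deterministic assignment of genes to programs, roles and markers."""
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    sizes = config.program_sizes
    bounds = np.cumsum((0,) + sizes)
    program_genes = {
        p: genes[bounds[i]: bounds[i + 1]] for i, p in enumerate(PROGRAMS)
    }
    # ferroptosis genes: some inside each program, the rest from the free pool
    ferro: list[str] = []
    for i, p in enumerate(PROGRAMS):
        ferro.extend(program_genes[p][: config.ferro_in_program[i]])
    n_ferro = (config.n_ferro_driver + config.n_ferro_suppressor
               + config.n_ferro_marker)
    free_start = bounds[-1]
    n_free_ferro = n_ferro - len(ferro)
    ferro.extend(genes[free_start: free_start + n_free_ferro])
    roles = {}
    role_seq = (["driver"] * config.n_ferro_driver
                + ["suppressor"] * config.n_ferro_suppressor
                + ["marker"] * config.n_ferro_marker)
    for g, r in zip(ferro, role_seq):
        roles[g] = r
    # mutation genes and cell-type markers from the remaining pool
    cursor = free_start + n_free_ferro
    mutation_genes = genes[cursor: cursor + config.n_mutation_genes]
    cursor += config.n_mutation_genes
    type_markers = {}
    for t in CELL_TYPES:
        type_markers[t] = genes[cursor: cursor + config.n_type_markers]
        cursor += config.n_type_markers
    return {
        "genes": genes,
        "program_genes": program_genes,
        "ferro_genes": ferro,
        "roles": roles,
        "mutation_genes": mutation_genes,
        "type_markers": type_markers,
    }


def _ferro_collection(structure: dict) -> GeneSetCollection:
    roles = structure["roles"]
    by_role: dict[str, list[str]] = {"driver": [], "suppressor": [], "marker": []}
    for g in structure["ferro_genes"]:
        by_role[roles[g]].append(g)
    sets = {f"FERROPTOSIS_{r.upper()}": members for r, members in by_role.items()}
    role_tags = {f"FERROPTOSIS_{r.upper()}": r for r in by_role}
    return GeneSetCollection(sets=sets, roles=role_tags)


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------


def simulate_bulk_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, MutationTable, GeneSetCollection, SimTruth]:
    """Bulk expression + survival + stage/MSI + mutations with known truth.

    Expression: per-gene uniform baseline (log2 scale) plus ``delta`` times a
    noisy per-sample program activity on that program's genes, plus
    N(0, sigma) noise, clipped at zero.  Survival: exponential with rate
    ``lambda0 * exp(beta_cluster)`` under uniform administrative censoring.
    """
    structure = _gene_structure(config)
    genes = structure["genes"]
    n, p = config.n_samples, config.n_genes
    samples = [f"S{i:03d}" for i in range(n)]

    rng_x = _rng(config, "expression")
    labels = rng_x.choice(3, size=n, p=np.asarray(config.mixing))
    # latent activity: 1 for the sample's own program, 0 otherwise; an
    # optional activity_sd blurs the indicator for soft-cluster scenarios
    activity = np.zeros((n, 3))
    if config.activity_sd > 0:
        activity += rng_x.normal(0.0, config.activity_sd, size=(n, 3))
    activity[np.arange(n), labels] += 1.0

    baseline = rng_x.uniform(*config.baseline_range, size=p)
    expr = np.tile(baseline[:, None], (1, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, prog in enumerate(PROGRAMS):
        idx = [gene_index[g] for g in structure["program_genes"][prog]]
        expr[np.ix_(idx, range(n))] += config.delta * activity[:, k][None, :]
    # TME infiltration visible in bulk: immune-cell markers track the immune
    # program (inflamed tumors), stromal-cell markers track the stromal one
    for t, k in (("T", 1), ("B", 1), ("myeloid", 1), ("stromal", 2)):
        idx = [gene_index[g] for g in structure["type_markers"][t]]
        expr[np.ix_(idx, range(n))] += config.delta * activity[:, k][None, :]
    expr += rng_x.normal(0.0, config.sigma, size=(p, n))
    np.clip(expr, 0.0, None, out=expr)
    X = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    # survival + clinical categories
    rng_s = _rng(config, "survival")
    betas = np.asarray(config.betas)
    rate = config.lambda0 * np.exp(betas[labels])
    t_event = rng_s.exponential(1.0 / rate)
    t_censor = rng_s.uniform(0.0, config.censor_max_days, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    stages = np.array(["I", "II", "III", "IV"])
    stage = np.array(
        [stages[rng_s.choice(4, p=np.asarray(config.stage_probs[c]))] for c in labels]
    )
    msi = np.array(
        ["MSI-H" if rng_s.random() < config.msi_high_probs[c] else "MSS"
         for c in labels]
    )
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": samples, "time": time, "event": event,
        "stage": stage, "msi": msi,
    }))

    # mutations: Bernoulli per (sample, mutation gene), immune cluster hotter
    rng_m = _rng(config, "mutation")
    rows = []
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
               "Splice_Site", "Silent"]
    class_p = np.array([0.55, 0.12, 0.10, 0.08, 0.15])
    for i, s in enumerate(samples):
        r = config.mutation_rate * (
            config.immune_mutation_multiplier if labels[i] == 1 else 1.0
        )
        hit = rng_m.random(len(structure["mutation_genes"])) < r
        for g in np.asarray(structure["mutation_genes"])[hit]:
            rows.append((s, g, classes[rng_m.choice(len(classes), p=class_p)]))
    mutations = MutationTable(pd.DataFrame(
        rows, columns=["sample_id", "gene_symbol", "variant_classification"]
    ))

    truth = SimTruth(
        cluster_labels=pd.Series(labels + 1, index=samples, name="cluster"),
        cluster_names={k + 1: PROGRAMS[k] for k in range(3)},
        program_genes=structure["program_genes"],
        ferroptosis_roles=structure["roles"],
        activity=pd.DataFrame(activity, index=samples, columns=list(PROGRAMS)),
        betas={PROGRAMS[k]: float(betas[k]) for k in range(3)},
        type_markers=structure["type_markers"],
    )
    return X, clinical, mutations, _ferro_collection(structure), truth


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------


def simulate_single_cell_cohort(config: SimConfig) -> tuple[SingleCellMatrix, SimTruth]:
    """Negative-binomial counts for five cell types over the bulk gene universe.

    Cell-type marker genes are elevated ``sc_marker_fold``-fold; epithelial
    cells additionally carry the canonical or immune transcriptional program
    (half each) and stromal cells carry the stromal program, so the bulk
    programs are observable in the single-cell compartment.
    """
    structure = _gene_structure(config)
    genes = structure["genes"]
    rng = _rng(config, "single_cell")
    n_cells, p = config.n_cells, config.n_genes
    cells = [f"C{i:05d}" for i in range(n_cells)]
    types = rng.choice(len(CELL_TYPES), size=n_cells,
                       p=np.asarray(config.cell_type_props))
    type_names = np.asarray(CELL_TYPES)[types]
    # epithelial program state: canonical or immune, half each
    states = np.where(rng.random(n_cells) < 0.5, "canonical", "immune")
    states = np.where(type_names == "epithelial", states, "none")

    base_mean = 2.0 ** rng.uniform(-4.0, 1.0, size=p)  # 0.06 .. 2 counts
    gene_index = {g: i for i, g in enumerate(genes)}
    fold = np.ones((p, n_cells))
    for t in CELL_TYPES:
        idx = [gene_index[g] for g in structure["type_markers"][t]]
        fold[np.ix_(idx, np.flatnonzero(type_names == t))] = config.sc_marker_fold
    prog_of_state = {"canonical": "canonical", "immune": "immune"}
    for state, prog in prog_of_state.items():
        idx = [gene_index[g] for g in structure["program_genes"][prog]]
        cols = np.flatnonzero((type_names == "epithelial") & (states == state))
        fold[np.ix_(idx, cols)] = config.sc_marker_fold
    idx = [gene_index[g] for g in structure["program_genes"]["stromal"]]
    fold[np.ix_(idx, np.flatnonzero(type_names == "stromal"))] = config.sc_marker_fold

    libsize = np.exp(rng.normal(0.0, config.sc_libsize_sd, size=n_cells))
    mu = base_mean[:, None] * fold * libsize[None, :]
    theta = config.sc_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    mat = SingleCellMatrix(
        counts=scipy.sparse.csr_matrix(counts),
        gene_ids=genes,
        cell_ids=cells,
        cell_meta=pd.DataFrame({
            "cell_id": cells, "cell_type": type_names, "program_state": states,
        }).set_index("cell_id"),
    )
    truth = SimTruth(
        program_genes=structure["program_genes"],
        ferroptosis_roles=structure["roles"],
        cell_types=pd.Series(type_names, index=cells, name="cell_type"),
        cell_states=pd.Series(states, index=cells, name="program_state"),
        type_markers=structure["type_markers"],
    )
    return mat, truth


# ---------------------------------------------------------------------------
# immunotherapy cohort
# ---------------------------------------------------------------------------


def simulate_icb_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Checkpoint-blockade cohort: response follows the immune-stromal axis.

    Latent immune and stromal activities are continuous N(0,1); response is
    Bernoulli(sigmoid(gamma * (immune - stromal))) and the post-treatment
    hazard is multiplied by exp(icb_response_log_hr) for responders.
    """
    structure = _gene_structure(config)
    genes = structure["genes"]
    rng = _rng(config, "icb")
    n, p = config.icb_n_samples, config.n_genes
    samples = [f"ICB{i:03d}" for i in range(n)]

    act = rng.normal(0.0, 1.0, size=(n, 3))  # canonical, immune, stromal
    baseline = rng.uniform(*config.baseline_range, size=p)
    expr = np.tile(baseline[:, None], (1, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, prog in enumerate(PROGRAMS):
        idx = [gene_index[g] for g in structure["program_genes"][prog]]
        expr[np.ix_(idx, range(n))] += config.delta * act[:, k][None, :]
    expr += rng.normal(0.0, config.sigma, size=(p, n))
    np.clip(expr, 0.0, None, out=expr)
    X = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))

    logit = config.icb_gamma * (act[:, 1] - act[:, 2])
    prob = 1.0 / (1.0 + np.exp(-logit))
    response = (rng.random(n) < prob).astype(int)
    rate = config.lambda0 * np.exp(config.icb_response_log_hr * response)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, config.censor_max_days, size=n)
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "time": np.minimum(t_event, t_censor),
        "event": (t_event <= t_censor).astype(int),
        "response": response,
    }))
    truth = SimTruth(
        program_genes=structure["program_genes"],
        ferroptosis_roles=structure["roles"],
        activity=pd.DataFrame(act, index=samples, columns=list(PROGRAMS)),
        response_prob=pd.Series(prob, index=samples, name="response_prob"),
    )
    return X, clinical, truth
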