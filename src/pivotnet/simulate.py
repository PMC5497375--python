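"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be generated here: a stage-wise
expression matrix with planted co-expressed modules, pivot genes and
differentially expressed genes; a protein-interaction edge list with planted
intra-module wiring and hub genes; flat GO-style annotations; three-way
differential-expression set fixtures with exact intersection cardinalities;
and centrosome-abnormality count tables.

The expression model is a latent-profile model on the log2 scale: each
planted module m draws one per-stage mean profile; a member gene's
log2-expression is its own baseline plus the module profile plus i.i.d.
Gaussian replicate noise, exponentiated to a nonnegative abundance.  The
profile standard deviation is chosen from the requested within-module
correlation strength c so that the expected pairwise Pearson correlation of
two members across samples is ~ c (shared-variance fraction
tau^2 / (tau^2 + sigma^2) = c).  Background genes carry baseline plus noise
only, so their expected pairwise correlation is zero.

Planted pivot genes are not members of any module; their expression tracks a
target module's profile (with configurable sign, emulating correlated and
anti-correlated crosstalk) so that their interaction edges into that module
survive the co-expression significance filter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "EMBRYO_STAGES",
    "SyntheticTruth",
    "generate_stage_expression",
    "generate_ppi",
    "generate_go_annotations",
    "generate_venn_fixture",
    "generate_centrosome_counts",
]

#: The seven preimplantation developmental stages used as default conditions.
EMBRYO_STAGES = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "blastocyst")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``module_assignments`` maps planted-module member genes to their module
    index; genes absent from the map are background.  ``pivot_genes`` lists
    (gene id, target module index, profile sign).  ``de_genes`` maps a
    contrast ``(stage_a, stage_b)`` to ``{gene: (direction, fold_change)}``
    where direction ``"up"`` means higher in ``stage_b``.
    """

    genes: list[str]
    module_assignments: dict[str, int]
    pivot_genes: list[tuple[str, int, int]]
    de_genes: dict[tuple[str, str], dict[str, tuple[str, float]]]
    seed: int
    companions: dict[str, str] = field(default_factory=dict)

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_assignments.items() if m == module]

    @property
    def n_modules(self) -> int:
        return max(self.module_assignments.values(), default=-1) + 1

    @property
    def background_genes(self) -> list[str]:
        planted = set(self.module_assignments) | {g for g, _, _ in self.pivot_genes}
        planted |= set(self.companions)
        return [g for g in self.genes if g not in planted]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "module_assignments": self.module_assignments,
            "pivot_genes": [list(t) for t in self.pivot_genes],
            "de_genes": {
                f"{a}_vs_{b}": {g: list(v) for g, v in d.items()}
                for (a, b), d in self.de_genes.items()
            },
            "companions": self.companions,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _profile_sd(strength: float, noise_sd: float) -> float:
    """Profile SD giving expected within-module PCC = strength."""
    if noise_sd == 0 or strength >= 1:
        return 1.0
    if not 0 < strength < 1:
        raise ValueError(f"correlation strength must be in (0, 1]: {strength}")
    return noise_sd * np.sqrt(strength / (1.0 - strength))


def generate_stage_expression(
    n_genes: int = 1000,
    stages=EMBRYO_STAGES,
    replicates_per_stage: int = 3,
    modules=((20, 0.9), (20, 0.9)),
    de_spec=None,
    noise_sd: float = 0.5,
    n_pivots: int = 3,
    pivot_companions: int = 0,
    baseline_log2: float = 6.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a stage-wise expression matrix with planted structure.

    Parameters
    ----------
    modules:
        Sequence of ``(size, within-module correlation strength)`` pairs.
    de_spec:
        Mapping ``(stage_a, stage_b) -> (n_de, fold_change)``; planted DE
        genes are drawn from the background and shifted by ±log2(fold_change)
        in ``stage_b`` (half up, half down).  Defaults to 10 genes at fold
        change 3.0 between the 4-cell and 8-cell stages.
    n_pivots:
        Number of planted pivot genes, assigned round-robin to modules with
        alternating profile sign (+1 correlated, -1 anti-correlated).
    pivot_companions:
        If > 0, each pivot additionally gets this many companion background
        genes sharing a pivot-private latent profile mixed with the target
        module profile.  Companions give the pivot its own co-expression
        neighbourhood (see :func:`generate_ppi`), emulating hubs whose MCL
        cluster is small and not GO-enriched.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("stages must be nonempty")
    if replicates_per_stage < 2:
        raise ValueError("replicates_per_stage must be >= 2 (correlation undefined)")
    module_sizes = [int(s) for s, _ in modules]
    if sum(module_sizes) + n_pivots * (1 + pivot_companions) > n_genes:
        raise ValueError(
            f"module sizes {module_sizes} plus {n_pivots} pivots exceed n_genes={n_genes}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if de_spec is None:
        de_spec = {("4cell", "8cell"): (10, 3.0)}
    for (a, b) in de_spec:
        for s in (a, b):
            if s not in stages:
                raise ValueError(f"DE contrast stage {s!r} not among stages")

    rng = np.random.default_rng(seed)
    n_stages = len(stages)
    sample_ids = [f"{s}_r{r + 1}" for s in stages for r in range(replicates_per_stage)]
    stage_of_col = np.repeat(np.arange(n_stages), replicates_per_stage)

    # gene naming: deterministic prefixes so truth lookup never collides
    gene_ids: list[str] = []
    module_assignments: dict[str, int] = {}
    for m, size in enumerate(module_sizes):
        for i in range(size):
            g = f"M{m}G{i:03d}"
            gene_ids.append(g)
            module_assignments[g] = m
    pivot_genes: list[tuple[str, int, int]] = []
    companions: dict[str, str] = {}
    for p in range(n_pivots):
        target = p % max(len(module_sizes), 1)
        sign = 1 if p % 2 == 0 else -1
        pid = f"PVT{p}"
        gene_ids.append(pid)
        pivot_genes.append((pid, target, sign))
        for c in range(pivot_companions):
            cid = f"PVT{p}C{c:02d}"
            gene_ids.append(cid)
            companions[cid] = pid
    n_background = n_genes - len(gene_ids)
    gene_ids += [f"BG{i:03d}" for i in range(n_background)]

    n_samples = n_stages * replicates_per_stage
    log2x = np.empty((n_genes, n_samples))
    baselines = rng.normal(baseline_log2, 1.0, size=n_genes)
    log2x[:] = baselines[:, None]

    def _scale(v: np.ndarray, tau: float) -> np.ndarray:
        # fix the realized spread so planted correlation strengths are
        # achieved by construction, not merely in expectation (with only a
        # handful of stages the realized variance of a raw draw fluctuates
        # enough to wash out planted structure for whole modules at once)
        v = v - v.mean()
        sd = v.std()
        return v if sd == 0 else v * (tau / sd)

    # module profiles: one per-stage mean vector per module
    profiles = []
    for m, (size, strength) in enumerate(modules):
        tau = _profile_sd(strength, noise_sd)
        profiles.append(_scale(rng.normal(0.0, tau, size=n_stages), tau))
    # pivot-private profiles (used when companions are planted), made
    # orthogonal to the target module profile so pivot-module correlations
    # are not randomly cancelled by the private component
    pivot_profiles = {}
    for pid, target, _sign in pivot_genes:
        tau = _profile_sd(0.9, noise_sd)
        v = rng.normal(0.0, tau, size=n_stages)
        if profiles:
            base = profiles[target]
            denom = float(base @ base)
            if denom > 0:
                v = v - (float(v @ base) / denom) * base
        pivot_profiles[pid] = _scale(v, tau)

    index = {g: i for i, g in enumerate(gene_ids)}
    for g, m in module_assignments.items():
        log2x[index[g]] += profiles[m][stage_of_col]
    for pid, target, sign in pivot_genes:
        if profiles:
            if pivot_companions > 0:
                # module-tracking component strong enough that in-module
                # edges are robustly significant, plus a pivot-private
                # component shared with the companions so the pivot's MCL
                # flow stays in its own small neighbourhood
                mix = 2.0 * sign * profiles[target] + pivot_profiles[pid]
            else:
                mix = sign * profiles[target]
            log2x[index[pid]] += mix[stage_of_col]
    for cid, pid in companions.items():
        target = next(t for p, t, _ in pivot_genes if p == pid)
        sign = next(s for p, _, s in pivot_genes if p == pid)
        mix = 2.0 * sign * profiles[target] + pivot_profiles[pid]
        log2x[index[cid]] += mix[stage_of_col]

    # planted differential expression, drawn from pure-background genes
    de_truth: dict[tuple[str, str], dict[str, tuple[str, float]]] = {}
    reserved = set(module_assignments) | {p for p, _, _ in pivot_genes} | set(companions)
    pool = [g for g in gene_ids if g not in reserved]
    for contrast, (n_de, fc) in de_spec.items():
        if fc <= 1:
            raise ValueError(f"planted fold change must be > 1: {fc}")
        if n_de > len(pool):
            raise ValueError("not enough background genes to plant DE genes")
        chosen = [pool[i] for i in rng.choice(len(pool), size=n_de, replace=False)]
        pool = [g for g in pool if g not in set(chosen)]
        b_cols = np.flatnonzero(stage_of_col == stages.index(contrast[1]))
        per_gene: dict[str, tuple[str, float]] = {}
        for j, g in enumerate(chosen):
            direction = "up" if j % 2 == 0 else "down"
            shift = np.log2(fc) if direction == "up" else -np.log2(fc)
            log2x[index[g], b_cols] += shift
            per_gene[g] = (direction, float(fc))
        de_truth[contrast] = per_gene

    if noise_sd > 0:
        log2x += rng.normal(0.0, noise_sd, size=log2x.shape)

    values = pd.DataFrame(np.exp2(log2x), index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "stage": [stages[s] for s in stage_of_col],
            "replicate": [r + 1 for _ in stages for r in range(replicates_per_stage)],
        },
        index=sample_ids,
    )
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=gene_ids,
                        name="length")
    expr = ExpressionMatrix(values, samples, units="counts", lengths=lengths)
    truth = SyntheticTruth(
        genes=gene_ids,
        module_assignments=module_assignments,
        pivot_genes=pivot_genes,
        de_genes=de_truth,
        seed=seed,
        companions=companions,
    )
    return expr, truth


def generate_ppi(
    truth: SyntheticTruth,
    p_within: float = 0.9,
    p_hub_to_module: float = 0.5,
    p_background: float = 0.01,
    hub_min_degree: int = 10,
    hub_out_edges: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a BioGrid-like interaction edge list around the planted truth.

    Intra-module gene pairs are wired with probability ``p_within``; each
    planted pivot is wired to ``round(p_hub_to_module * module_size)`` members
    of its target module (topped up so total degree >= ``hub_min_degree``)
    plus ``hub_out_edges`` genes outside the module; remaining pairs get
    background noise edges with probability ``p_background``.  When the truth
    carries companion genes, a pivot's out-edges go to its companions (which
    are also wired among themselves), giving the pivot a private
    co-expression neighbourhood.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``,
    ``interaction_type``; no self-edges, no duplicates in either orientation.
    """
    for name, p in [("p_within", p_within), ("p_hub_to_module", p_hub_to_module),
                    ("p_background", p_background)]:
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]: {p}")
    if p_within <= p_background and p_within != 0:
        raise ValueError("p_within must exceed p_background")

    rng = np.random.default_rng(seed)
    edges: dict[frozenset, str] = {}

    def add(u: str, v: str, kind: str) -> None:
        if u == v:
            return
        key = frozenset((u, v))
        if key not in edges:
            edges[key] = kind

    for m in range(truth.n_modules):
        members = truth.module_members(m)
        for u, v in itertools.combinations(members, 2):
            if rng.random() < p_within:
                add(u, v, "physical")

    pivot_ids = {p for p, _, _ in truth.pivot_genes}
    for pid, target, _sign in truth.pivot_genes:
        members = truth.module_members(target)
        k_in = int(round(p_hub_to_module * len(members)))
        own = [c for c, p in truth.companions.items() if p == pid]
        n_out = len(own) if own else hub_out_edges
        k_in = min(len(members), max(k_in, hub_min_degree - n_out))
        chosen = rng.choice(len(members), size=k_in, replace=False)
        for i in chosen:
            add(pid, members[i], "physical")
        if own:
            for c in own:
                add(pid, c, "physical")
            for u, v in itertools.combinations(own, 2):
                if rng.random() < p_within:
                    add(u, v, "physical")
        else:
            outside = [g for g in truth.genes
                       if g not in set(members) and g != pid and g not in pivot_ids]
            for i in rng.choice(len(outside), size=min(hub_out_edges, len(outside)),
                                replace=False):
                add(pid, outside[i], "genetic")

    if p_background > 0:
        genes = truth.genes
        iu, ju = np.triu_indices(len(genes), k=1)
        hits = np.flatnonzero(rng.random(iu.size) < p_background)
        for t in hits:
            add(genes[iu[t]], genes[ju[t]], "genetic")

    rows = sorted((tuple(sorted(k)), kind) for k, kind in edges.items())
    return pd.DataFrame(
        [(a, b, kind) for (a, b), kind in rows],
        columns=["gene_a", "gene_b", "interaction_type"],
    )


def generate_go_annotations(
    truth: SyntheticTruth,
    terms_per_module: int = 2,
    annotation_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a flat gene -> GO-term annotation table.

    Each planted module gets ``terms_per_module`` private terms.  At
    ``annotation_noise = 0`` a module term annotates exactly the module
    members; at noise 1 annotation is an independent Bernoulli draw at the
    module's base rate, so enrichment p-values are uniform under the null.
    """
    if terms_per_module < 1:
        raise ValueError("terms_per_module must be >= 1")
    if not 0 <= annotation_noise <= 1:
        raise ValueError("annotation_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    n_genes = len(truth.genes)
    for m in range(truth.n_modules):
        members = set(truth.module_members(m))
        base_rate = len(members) / n_genes
        for t in range(terms_per_module):
            term = f"GO:M{m}T{t}"
            for g in truth.genes:
                signal = g in members
                if rng.random() < annotation_noise:
                    annotated = rng.random() < base_rate
                else:
                    annotated = signal
                if annotated:
                    rows.append((g, term))
    return pd.DataFrame(rows, columns=["gene", "term"])


_REGION_NAMES = {
    "abc": "A∩B∩C",
    "ab": "A∩B exclusive",
    "ac": "A∩C exclusive",
    "bc": "B∩C exclusive",
    "a": "A exclusive",
    "b": "B exclusive",
    "c": "C exclusive",
}


def generate_venn_fixture(
    set_sizes: tuple[int, int, int],
    pairwise_intersections: tuple[int, int, int],
    triple_intersection: int,
    universe_prefix: str = "g",
) -> tuple[set, set, set]:
    """Construct three gene sets with exact Venn cardinalities.

    ``pairwise_intersections`` is ``(|A∩B|, |A∩C|, |B∩C|)`` INCLUSIVE of the
    triple region.  Raises ``ValueError`` naming the violated region when the
    requested cardinalities are infeasible.
    """
    a, b, c = set_sizes
    ab, ac, bc = pairwise_intersections
    t = triple_intersection
    regions = {
        "abc": t,
        "ab": ab - t,
        "ac": ac - t,
        "bc": bc - t,
        "a": a - ab - ac + t,
        "b": b - ab - bc + t,
        "c": c - ac - bc + t,
    }
    for key, size in regions.items():
        if size < 0:
            raise ValueError(
                f"infeasible Venn specification: region {_REGION_NAMES[key]} "
                f"would have {size} elements"
            )
    members = {
        key: {f"{universe_prefix}_{key}_{i:04d}" for i in range(size)}
        for key, size in regions.items()
    }
    set_a = members["a"] | members["ab"] | members["ac"] | members["abc"]
    set_b = members["b"] | members["ab"] | members["bc"] | members["abc"]
    set_c = members["c"] | members["ac"] | members["bc"] | members["abc"]
    return set_a, set_b, set_c


def generate_centrosome_counts(
    conditions,
    true_proportions,
    n_range: tuple[int, int] = (250, 270),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-condition cell counts with supernumerary centrosomes.

    For each condition the number of cells counted is uniform on ``n_range``
    (default 250-270 cells) and the number of cells with more than two
    centrosomes is Binomial(n, p) at the condition's true proportion.
    """
    conditions = list(conditions)
    true_proportions = list(true_proportions)
    if len(conditions) != len(true_proportions):
        raise ValueError("conditions and true_proportions must have equal length")
    for p in true_proportions:
        if not 0 <= p <= 1:
            raise ValueError(f"proportion out of [0, 1]: {p}")
    lo, hi = n_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid n_range: {n_range}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, p in zip(conditions, true_proportions):
        n = int(rng.integers(lo, hi + 1))
        k = int(rng.binomial(n, p))
        rows.append((cond, n, k))
    return pd.DataFrame(rows, columns=["condition", "n_counted", "n_abnormal"])
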