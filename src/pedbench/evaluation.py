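"""Scoring embeddings against ancestral ground truth, and popgen summaries.

The scoring protocol: for an embedding of n individuals, compute all
pairwise Euclidean distances, optionally take log2 (the "exponential with
depth" reading, under which a grandparent sits at the squared distance of
a parent), and report Pearson's r against the ground-truth ancestral
distance over the pairs for which the truth is defined.  Replicated over
many simulations, methods are then compared with a one-way ANOVA plus
Tukey HSD, summarized as a compact letter display.

Population-genetic summaries: multi-population Weir–Cockerham θ (F_ST)
combined across loci as a ratio of sums, and per-site MAF / observed
heterozygosity / Hardy–Weinberg χ² (1 df).
"""

from __future__ import annotations

import string
import warnings
import zlib
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy import stats

from .embeddings import (EmbeddingResult, GenotypeMatrix, NeuralConfig,
                         METHODS, embed)
from .ground_truth import (GroundTruthDistances, a_matrix, ibd_distance,
                           pedigree_path_distance)
from .simulator import SimulationConfig, simulate

__all__ = [
    "CorrelationResult",
    "BenchmarkReport",
    "SCENARIOS",
    "distance_correlation",
    "fst",
    "site_summaries",
    "tukey_cld",
    "run_benchmark",
]

TRANSFORMS = ("D", "log2D")
TRUTHS = ("pedigree", "ibd")

#: Scenario name -> SimulationConfig overrides
SCENARIOS: dict[str, dict] = {
    "migration_random": {"migration_enabled": True, "mating": "random"},
    "migration_assortative": {"migration_enabled": True, "mating": "assortative"},
    "no_migration_random": {"migration_enabled": False, "mating": "random"},
    "no_migration_assortative": {"migration_enabled": False, "mating": "assortative"},
}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r of one (embedding, truth, transform) combination."""

    method: str
    truth: str
    transform: str
    r: float
    n_pairs: int
    scenario: str = ""
    rep: int = 0

    def __post_init__(self):
        if not (np.isnan(self.r) or -1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"Pearson r out of range: {self.r}")


def distance_correlation(emb: EmbeddingResult, truth: GroundTruthDistances,
                         transform: str = "D") -> CorrelationResult:
    """Pearson r between embedding distance (or log2 of it) and ground truth.

    Only pairs with a defined ground-truth value enter the correlation.
    Zero embedding distances are clamped to the smallest positive normal
    double before log2, so the D and log2(D) columns always use the same
    pairs.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    pos = {x: i for i, x in enumerate(emb.ids)}
    try:
        idx = np.asarray([pos[x] for x in truth.ids])
    except KeyError as e:
        raise ValueError(f"embedding lacks individual {e.args[0]!r}") from None
    d = pdist(emb.coords[idx])
    mask = truth.defined_mask
    if mask.sum() < 3:
        raise ValueError("fewer than 3 defined ground-truth pairs")
    d = d[mask]
    t = truth.values[mask]
    if transform == "log2D":
        d = np.log2(np.maximum(d, np.finfo(np.float64).tiny))
    if np.std(d) == 0 or np.std(t) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(d, t)[0, 1])
    return CorrelationResult(method=emb.method, truth=truth.metric,
                             transform=transform, r=r, n_pairs=int(mask.sum()))


# ---------------------------------------------------------------------------
# population-genetic summaries
# ---------------------------------------------------------------------------

def fst(X: GenotypeMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Multi-population Weir–Cockerham θ, ratio-of-sums across loci.

    Per locus the variance components are (r subpopulations, sample sizes
    n_i, allele frequencies p_i, heterozygote fractions h_i)::

        a = n̄/n_c [ s² − (p̄(1−p̄) − (r−1)/r s² − h̄/4) / (n̄−1) ]
        b = n̄/(n̄−1) [ p̄(1−p̄) − (r−1)/r s² − (2n̄−1)/(4n̄) h̄ ]
        c = h̄/2

    with θ = Σa / Σ(a+b+c) over polymorphic loci (monomorphic skipped).
    """
    vals = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    labels = np.asarray(labels)
    if labels.shape[0] != vals.shape[0]:
        raise ValueError("labels must align with genotype rows")
    groups = np.unique(labels)
    r = groups.size
    if r < 2:
        raise ValueError("F_ST requires at least 2 subpopulations")
    n_i = np.array([(labels == g).sum() for g in groups], dtype=np.float64)
    if np.any(n_i < 2):
        raise ValueError("each subpopulation needs at least 2 individuals")
    # per-subpop alt-allele frequency and heterozygote fraction, per locus
    p = np.empty((r, vals.shape[1]))
    h = np.empty((r, vals.shape[1]))
    for k, g in enumerate(groups):
        sub = vals[labels == g]
        p[k] = sub.mean(axis=0) / 2.0
        h[k] = (sub == 1).mean(axis=0)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    poly = (pbar > 0) & (pbar < 1)
    denom = (a + b + c)[poly].sum()
    if denom == 0:
        raise ValueError("no informative loci for F_ST")
    return float(a[poly].sum() / denom)


def site_summaries(X: GenotypeMatrix | np.ndarray) -> pd.DataFrame:
    """Per-site MAF, observed heterozygosity and 1-df Hardy–Weinberg χ²."""
    vals = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    n1 = (vals == 1).sum(axis=0)
    n2 = (vals == 2).sum(axis=0)
    n0 = n - n1 - n2
    q = (n1 + 2 * n2) / (2.0 * n)
    maf = np.minimum(q, 1 - q)
    het_obs = n1 / n
    exp = np.stack([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2])
    obs = np.stack([n0, n1, n2]).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
    chi2 = terms.sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({"maf": maf, "het_obs": het_obs,
                         "hwe_chi2": chi2, "hwe_p": pval})


# ---------------------------------------------------------------------------
# Tukey HSD compact letter display
# ---------------------------------------------------------------------------

def tukey_cld(results: pd.DataFrame, alpha: float = 0.05,
              value_col: str = "r", group_col: str = "method") -> dict[str, str]:
    """One-way ANOVA + Tukey HSD, summarized as compact letters.

    Groups sharing a letter are not significantly different at ``alpha``.
    Uses the standard insert-and-absorb construction; letters are assigned
    in order of descending group mean.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = results[group_col].astype(str).to_numpy()
    values = results[value_col].to_numpy(dtype=np.float64)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    per = [values[groups == g] for g in names]
    if any(len(v) < 2 for v in per):
        raise ValueError("need at least 2 replicates per group")
    if all(np.var(v) == 0 for v in per):
        raise ValueError("zero within-group variance everywhere; "
                         "Tukey HSD undefined")
    stats.f_oneway(*per)  # ANOVA context; letters come from the HSD tests
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(hsd.summary().data[1:],
                         columns=hsd.summary().data[0])
    sig_pairs = [(str(row["group1"]), str(row["group2"]))
                 for _, row in frame.iterrows() if row["reject"] in (True, "True")]

    letters: list[set[str]] = [set(names)]
    for g1, g2 in sig_pairs:
        for L in [L for L in letters if g1 in L and g2 in L]:
            letters.remove(L)
            for drop in (g1, g2):
                cand = L - {drop}
                if cand and not any(cand <= other for other in letters):
                    letters.append(cand)
    # absorb redundant subsets
    letters = [L for L in letters
               if not any(L < other for other in letters)]
    means = {g: float(np.mean(v)) for g, v in zip(names, per)}
    letters.sort(key=lambda L: -max(means[g] for g in L))
    order = sorted(names, key=lambda g: -means[g])
    alphabet = string.ascii_lowercase
    out = {g: "" for g in names}
    for i, L in enumerate(letters):
        ch = alphabet[i % len(alphabet)]
        for g in order:
            if g in L:
                out[g] += ch
    return out


# ---------------------------------------------------------------------------
# the multi-replicate benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-replicate correlations plus the aggregated mean ± SD + CLD table."""

    results: pd.DataFrame          # long form: one row per scored cell
    summary: pd.DataFrame          # mean, sd, letters per cell
    fst_per_rep: pd.DataFrame      # scenario, rep, fst
    seed: int

    def table(self, truth: str = "pedigree") -> pd.DataFrame:
        """Wide table shaped like the published benchmark: rows = method,
        columns = scenario × transform, cells = 'mean (± sd) letters'."""
        sub = self.summary[self.summary["truth"] == truth]
        cells = sub.assign(cell=[f"{m:.2f} (± {s:.2f}) {l}" for m, s, l in
                                 zip(sub["mean_r"], sub["sd_r"], sub["letters"])])
        return cells.pivot(index="method", columns=["transform", "scenario"],
                           values="cell")


def ground_truths_for(result, truths=TRUTHS) -> dict[str, GroundTruthDistances]:
    """Both ground-truth distance sets over a simulation's terminal individuals."""
    out = {}
    terminal = result.terminal_ids
    if "pedigree" in truths:
        out["pedigree"] = pedigree_path_distance(result.pedigree, terminal)
    if "ibd" in truths:
        A = a_matrix(result.pedigree)
        out["ibd"] = ibd_distance(A, result.pedigree.ids, subset=terminal)
    return out


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_benchmark(scenarios=("migration_random",), methods=("pca",),
                  truths=TRUTHS, transforms=TRANSFORMS, n_reps: int = 1,
                  seed: int = 0, base_config: SimulationConfig | None = None,
                  neural_cfg: NeuralConfig | None = None,
                  progress: bool = False) -> BenchmarkReport:
    """Simulate, embed and score every scenario × replicate × method cell.

    Per replicate one simulation is run and shared by all methods; the D
    and log2(D) columns are computed from the same embedding (no re-fit).
    Between-subpopulation F_ST is recorded per replicate where the
    terminal generation has ≥ 2 subpopulations.  Fully reproducible from
    ``seed``.
    """
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    base = base_config or SimulationConfig()
    rows, fst_rows = [], []
    for scenario in scenarios:
        sc_tag = zlib.crc32(scenario.encode()) & 0xFFFF
        for rep in range(n_reps):
            config = dc_replace(
                base, seed=_child_seed(np.random.SeedSequence((seed, sc_tag, rep))),
                **SCENARIOS[scenario])
            result = simulate(config)
            if progress:
                print(f"[{scenario} rep {rep}] n_terminal="
                      f"{result.genotypes.n_individuals} "
                      f"n_subpops={np.unique(result.subpop_labels).size}",
                      flush=True)
            gts = ground_truths_for(result, truths)
            labels = result.subpop_labels
            uniq, counts = np.unique(labels, return_counts=True)
            big = np.isin(labels, uniq[counts >= 2])
            if uniq[counts >= 2].size >= 2:
                try:
                    fst_rows.append({"scenario": scenario, "rep": rep,
                                     "fst": fst(result.genotypes.values[big],
                                                labels[big])})
                except ValueError:
                    pass
            for mi, method in enumerate(methods):
                mseed = _child_seed(np.random.SeedSequence(
                    (seed, sc_tag, rep, mi)))
                try:
                    emb = embed(result.genotypes, method, seed=mseed,
                                cfg=neural_cfg)
                except Exception as e:  # a failed method is recorded, not fatal
                    warnings.warn(f"{method} failed on {scenario} rep {rep}: {e}")
                    for truth in gts:
                        for tr in transforms:
                            rows.append({"scenario": scenario, "rep": rep,
                                         "method": method, "truth": truth,
                                         "transform": tr, "r": np.nan,
                                         "n_pairs": 0})
                    continue
                for truth, gt in gts.items():
                    for tr in transforms:
                        cr = distance_correlation(emb, gt, tr)
                        rows.append({"scenario": scenario, "rep": rep,
                                     "method": method, "truth": truth,
                                     "transform": tr, "r": cr.r,
                                     "n_pairs": cr.n_pairs})
    results = pd.DataFrame(rows)
    fst_df = pd.DataFrame(fst_rows, columns=["scenario", "rep", "fst"])
    agg = (results.groupby(["scenario", "method", "truth", "transform"],
                           as_index=False)
           .agg(mean_r=("r", "mean"), sd_r=("r", "std"), n=("r", "size")))
    agg["sd_r"] = agg["sd_r"].fillna(0.0)
    agg["letters"] = ""
    if len(methods) >= 2 and n_reps >= 2:
        for (scenario, truth, tr), _ in agg.groupby(["scenario", "truth",
                                                     "transform"]):
            cell = results[(results["scenario"] == scenario)
                           & (results["truth"] == truth)
                           & (results["transform"] == tr)].dropna(subset=["r"])
            try:
                letters = tukey_cld(cell)
            except ValueError:
                continue
            sel = ((agg["scenario"] == scenario) & (agg["truth"] == truth)
                   & (agg["transform"] == tr))
            agg.loc[sel, "letters"] = agg.loc[sel, "method"].map(letters)
    return BenchmarkReport(results=results, summary=agg, fst_per_rep=fst_df,
                           seed=seed)
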