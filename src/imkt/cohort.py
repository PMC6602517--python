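"""Multi-gene analysis: concatenation, heterogeneity tests and bootstrap
comparison of adaptation rates between gene sets.

Concatenating genes (summing spectra and divergence counts) estimates the
selection regimes of a gene set as a whole, which stabilizes alpha for genes
with few segregating sites. Whether selection is homogeneous across the set
is assessed on the per-gene 2x2 tables (strata): the Cochran-Mantel-Haenszel
statistic tests for a common polymorphism/divergence association, and the
Breslow-Day-Tarone statistic tests whether the per-gene odds ratios are
homogeneous. Group-versus-group comparisons resample genes with replacement
within each group, re-estimate alpha per replicate with the chosen MKT
variant, and report percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from . import asymptotic, mkt_core
from .types import (
    BootstrapComparison,
    BootstrapSummary,
    CmhResult,
    DafBin,
    DafTable,
    DivergenceSummary,
    GeneRecord,
    ValidationError,
)

#: common grid used when genes were sampled at different depths
REBIN_GRID_SIZE = 20


@dataclass
class MethodSpec:
    """Which MKT variant to run when estimating alpha for a gene set."""

    method: str = "standard"  # standard | fww | emkt | amkt
    cutoff: float = mkt_core.DEFAULT_CUTOFF
    x_interval: tuple[float, float] = asymptotic.DEFAULT_X_INTERVAL

    def estimate_alpha(self, daf: DafTable, div: DivergenceSummary) -> float | None:
        if self.method == "standard":
            return mkt_core.standard_mkt(daf, div).alpha
        if self.method == "fww":
            return mkt_core.fww_mkt(daf, div, self.cutoff).alpha
        if self.method == "emkt":
            return mkt_core.emkt(daf, div, self.cutoff).alpha
        if self.method == "amkt":
            try:
                traj = asymptotic.alpha_trajectory(daf, div)
                traj = asymptotic.trim(traj, *self.x_interval)
                return asymptotic.fit_asymptotic(traj, self.x_interval).alpha_asymptote
            except ValidationError:
                return None
        raise ValidationError(f"unknown method {self.method!r}")


def rebin(daf: DafTable, n_bins: int = REBIN_GRID_SIZE) -> DafTable:
    """Project a spectrum onto a common equal-width frequency grid.

    Bin i covers [i/n_bins, (i+1)/n_bins) and is represented by its centre
    frequency. Used before concatenating genes sampled at different depths.
    """
    pn = np.zeros(n_bins, dtype=int)
    ps = np.zeros(n_bins, dtype=int)
    for b in daf.bins:
        idx = min(int(b.daf * n_bins), n_bins - 1)
        pn[idx] += b.pn
        ps[idx] += b.ps
    bins = [
        DafBin((i + 0.5) / n_bins, int(pn[i]), int(ps[i])) for i in range(n_bins)
    ]
    return DafTable(n_sample=n_bins, bins=bins)


def concatenate(genes: Sequence[GeneRecord]) -> GeneRecord:
    """Sum spectra and divergence counts across genes.

    Genes sharing a sample depth are summed bin-wise on the i/n grid; mixed
    depths are first projected onto the common equal-width grid. Site totals
    are summed when known for every member, else left unknown.
    """
    if not genes:
        raise ValidationError("cannot concatenate an empty gene list")
    depths = {g.daf.n_sample for g in genes}
    if len(depths) == 1:
        tables = [g.daf for g in genes]
    else:
        tables = [rebin(g.daf) for g in genes]

    acc: dict[float, list[int]] = {}
    for t in tables:
        for b in t.bins:
            cell = acc.setdefault(b.daf, [0, 0])
            cell[0] += b.pn
            cell[1] += b.ps
    bins = [DafBin(d, c[0], c[1]) for d, c in sorted(acc.items())]
    daf = DafTable(n_sample=tables[0].n_sample, bins=bins)

    dn = sum(g.div.dn for g in genes)
    ds = sum(g.div.ds for g in genes)
    if all(g.div.has_site_totals for g in genes):
        m_n: float | None = sum(g.div.m_n for g in genes)  # type: ignore[misc]
        m_s: float | None = sum(g.div.m_s for g in genes)  # type: ignore[misc]
    else:
        m_n = m_s = None
    div = DivergenceSummary(dn=dn, ds=ds, m_n=m_n, m_s=m_s)
    return GeneRecord(
        gene_id="+".join(g.gene_id for g in genes[:3])
        + (f"+{len(genes) - 3}more" if len(genes) > 3 else ""),
        daf=daf,
        div=div,
        metadata={"n_genes": len(genes)},
    )


def _gene_stratum(g: GeneRecord) -> np.ndarray | None:
    """Per-gene 2x2 stratum [[pn, ps], [dn, ds]]; None when degenerate."""
    t = np.array(
        [[g.daf.pn_total, g.daf.ps_total], [g.div.dn, g.div.ds]], dtype=float
    )
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return None
    return t


def cmh_test(genes: Sequence[GeneRecord], variant: str = "common-association") -> CmhResult:
    """Stratified 2x2 test over per-gene MKT tables.

    ``common-association``: Cochran-Mantel-Haenszel chi-square (df=1, no
    continuity correction) for a shared polymorphism/divergence association.
    ``heterogeneity``: Breslow-Day test with the Tarone adjustment (df=K-1)
    for homogeneity of the per-gene odds ratios.
    """
    strata = [s for s in (_gene_stratum(g) for g in genes) if s is not None]
    k = len(strata)
    if k < 2:
        raise ValidationError("need >= 2 genes with nondegenerate 2x2 tables")
    if variant == "common-association":
        st = StratifiedTable(np.stack(strata, axis=-1))  # shape (2, 2, K)
        res = st.test_null_odds(correction=False)
        statistic, p, df = float(res.statistic), float(res.pvalue), 1
    elif variant == "heterogeneity":
        statistic, p = _breslow_day_tarone(strata)
        df = k - 1
    else:
        raise ValidationError(f"unknown CMH variant {variant!r}")
    return CmhResult(
        statistic=statistic, df=df, p_value=p, k_strata=k, variant=variant
    )


def _bd_expected_a(r1: float, c1: float, n: float, odds: float) -> float:
    """Expected top-left cell given margins and a common odds ratio.

    Solves a*(n - r1 - c1 + a) = odds*(r1 - a)*(c1 - a) for the feasible
    root; the quadratic degenerates to a linear equation when odds == 1.
    """
    aa = odds - 1.0
    bb = -(odds * (r1 + c1) + (n - r1 - c1))
    cc = odds * r1 * c1
    lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)
    if abs(aa) < 1e-12:
        return cc / -bb
    disc = max(bb * bb - 4.0 * aa * cc, 0.0)
    roots = ((-bb - np.sqrt(disc)) / (2 * aa), (-bb + np.sqrt(disc)) / (2 * aa))
    feasible = [r for r in roots if lo - 1e-9 <= r <= hi + 1e-9]
    if not feasible:  # numerical corner: fall back to the nearer root
        feasible = [min(roots, key=lambda r: abs(r - np.clip(r, lo, hi)))]
    return float(np.clip(feasible[0], lo, hi))


def _breslow_day_tarone(strata: Sequence[np.ndarray]) -> tuple[float, float]:
    """Breslow-Day homogeneity statistic with the Tarone adjustment.

    The common odds ratio is the Mantel-Haenszel estimate; per stratum the
    expected top-left cell under that common ratio is compared to the
    observed one, scaled by its asymptotic variance. Tarone's correction
    subtracts the (squared) summed deviation over the summed variance.
    """
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in strata)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in strata)
    if den == 0 or num == 0:
        raise ValidationError("Mantel-Haenszel odds ratio degenerate (0 or inf)")
    or_mh = num / den
    stat = 0.0
    dev_sum = 0.0
    var_sum = 0.0
    for t in strata:
        a = t[0, 0]
        r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
        a_tilde = _bd_expected_a(r1, c1, n, or_mh)
        cells = (a_tilde, r1 - a_tilde, c1 - a_tilde, n - r1 - c1 + a_tilde)
        inv_var = sum(1.0 / c for c in cells if c > 0)
        var = 1.0 / inv_var
        stat += (a - a_tilde) ** 2 / var
        dev_sum += a - a_tilde
        var_sum += var
    stat -= dev_sum**2 / var_sum  # Tarone adjustment
    stat = max(stat, 0.0)
    df = len(strata) - 1
    return float(stat), float(stats.chi2.sf(stat, df))


def bootstrap_alpha(
    genes: Sequence[GeneRecord],
    method_spec: MethodSpec,
    n_reps: int = 100,
    sample_size: int | None = None,
    seed: int = 0,
    label: str = "group",
) -> BootstrapSummary:
    """Bootstrap sampling distribution of alpha for one gene group.

    Each replicate draws ``sample_size`` genes with replacement, concatenates
    them and estimates alpha with ``method_spec``. Replicate streams are
    derived from (seed, replicate index), so results do not depend on gene
    iteration order elsewhere. Undefined replicate alphas are dropped and
    counted; losing more than 20% flags the summary.
    """
    if not genes:
        raise ValidationError("empty gene group")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if sample_size is None:
        sample_size = len(genes)
    if sample_size < 1:
        raise ValidationError("sample_size must be >= 1")

    alphas: list[float] = []
    n_dropped = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, len(genes), size=sample_size)
        sample = [genes[i] for i in idx]
        pooled = concatenate(sample)
        a = method_spec.estimate_alpha(pooled.daf, pooled.div)
        if a is None:
            n_dropped += 1
        else:
            alphas.append(a)

    if not alphas:
        raise ValidationError("every bootstrap replicate produced undefined alpha")
    arr = np.array(alphas)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return BootstrapSummary(
        label=label,
        replicate_alphas=alphas,
        n_reps=n_reps,
        n_dropped=n_dropped,
        sample_size=sample_size,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        flagged=n_dropped > 0.2 * n_reps,
    )


def compare_groups(
    group_a: Sequence[GeneRecord],
    group_b: Sequence[GeneRecord],
    method_spec: MethodSpec,
    n_reps: int = 100,
    sample_size: int | None = None,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> BootstrapComparison:
    """Bootstrap comparison of alpha between two gene groups.

    Both groups are resampled with shared settings but independent seeded
    streams; the difference (A - B) is summarized replicate-wise with a
    percentile CI. Comparing a subset against the whole-genome distribution
    is the special case ``group_b = full dataset``.
    """
    size_a = sample_size if sample_size is not None else len(group_a)
    size_b = sample_size if sample_size is not None else len(group_b)
    sa = bootstrap_alpha(group_a, method_spec, n_reps, size_a, seed=_substream(seed, 0), label=labels[0])
    sb = bootstrap_alpha(group_b, method_spec, n_reps, size_b, seed=_substream(seed, 1), label=labels[1])
    k = min(len(sa.replicate_alphas), len(sb.replicate_alphas))
    diffs = np.array(sa.replicate_alphas[:k]) - np.array(sb.replicate_alphas[:k])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapComparison(
        group_a=sa,
        group_b=sb,
        diff_mean=float(diffs.mean()),
        diff_ci_low=float(lo),
        diff_ci_high=float(hi),
        method=method_spec.method,
        cutoff=method_spec.cutoff,
        seed=seed,
    )


def _substream(seed: int, stream: int) -> int:
    """Derive an independent child seed below 2**31."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def filter_genes(
    dataset: Sequence[GeneRecord],
    min_recombination: float | None = None,
    chromosome: str | None = None,
    gene_ids: Iterable[str] | None = None,
    predicate: Callable[[GeneRecord], bool] | None = None,
    strict: bool = False,
) -> list[GeneRecord]:
    """Subset a gene dataset, preserving order.

    The recombination filter is strict (rate > threshold, in cM/Mb). Unknown
    ids in ``gene_ids`` produce a warning note unless ``strict``; a missing
    metadata key fails the gene unless ``strict`` (then it raises).
    """
    wanted = set(gene_ids) if gene_ids is not None else None
    if wanted is not None:
        known = {g.gene_id for g in dataset}
        unknown = wanted - known
        if unknown:
            if strict:
                raise ValidationError(f"unknown gene id(s): {sorted(unknown)}")
            import warnings

            warnings.warn(f"unknown gene id(s) ignored: {sorted(unknown)}")

    def _meta(g: GeneRecord, key: str):
        if key not in g.metadata:
            if strict:
                raise ValidationError(f"gene {g.gene_id}: missing metadata {key!r}")
            return None
        return g.metadata[key]

    out = []
    for g in dataset:
        if wanted is not None and g.gene_id not in wanted:
            continue
        if min_recombination is not None:
            rate = _meta(g, "recombination_rate")
            if rate is None or not float(rate) > min_recombination:
                continue
        if chromosome is not None and _meta(g, "chromosome") != chromosome:
            continue
        if predicate is not None and not predicate(g):
            continue
        out.append(g)
    return out
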