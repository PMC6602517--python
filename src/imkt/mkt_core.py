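"""Standard MKT, the FWW low-frequency correction, and the extended MKT.

The McDonald-Kreitman framework contrasts polymorphism and divergence at a
putatively selected site class (nonsynonymous, Pn/Dn) against a putatively
neutral one (synonymous, Ps/Ds). Under strict neutrality the two ratios are
equal; an excess of Dn relative to the polymorphism ratio signals recurrent
positive selection, summarized by

    alpha = 1 - (Ds * Pn) / (Dn * Ps)

Because weakly deleterious variants segregate at low frequency but rarely
fix, they inflate Pn and bias alpha downward. The FWW correction simply
drops all variants below a frequency cutoff. The extended MKT instead
partitions low-frequency Pn into a neutral part (in proportion to the
neutral spectrum) and a weakly deleterious remainder, substituting the
neutral part into the 2x2 table; with site totals m_n/m_s it also yields
the selection-regime fractions f (neutral), b (weakly deleterious) and
d (strongly deleterious) of selected sites.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import gammaln

from .types import (
    ContingencyTable2x2,
    DafTable,
    DivergenceSummary,
    MktResult,
    ValidationError,
)

DEFAULT_CUTOFF = 0.05

#: relative slack when comparing hypergeometric point probabilities; makes
#: floating-point ties inclusive, matching exact-arithmetic enumeration
_REL_SLACK = 1e-7


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for the MKT 2x2 table.

    Sums hypergeometric point probabilities no greater than that of the
    observed table. Small tables (total <= 400) use exact integer
    enumeration; larger ones (e.g. concatenated gene sets) use log-space
    arithmetic with a small relative slack so floating-point ties are
    included. A table with any zero margin carries no information and is
    assigned p = 1.
    """
    pn, ps, dn, ds = (int(round(v)) for v in (t.pn, t.ps, t.dn, t.ds))
    row1, row2 = pn + ps, dn + ds
    col1, col2 = pn + dn, ps + ds
    if min(row1, row2, col1, col2) == 0:
        return 1.0
    n_total = row1 + row2
    lo, hi = max(0, row1 - col2), min(row1, col1)

    if n_total <= 400:
        nums = [comb(col1, x) * comb(col2, row1 - x) for x in range(lo, hi + 1)]
        obs = nums[pn - lo]
        return min(sum(v for v in nums if v <= obs) / comb(n_total, row1), 1.0)

    # hypergeometric support for the top-left cell given the margins
    x = np.arange(lo, hi + 1)
    logp = (
        gammaln(col1 + 1)
        - gammaln(x + 1)
        - gammaln(col1 - x + 1)
        + gammaln(col2 + 1)
        - gammaln(row1 - x + 1)
        - gammaln(col2 - row1 + x + 1)
        + gammaln(row1 + 1)
        + gammaln(row2 + 1)
        - gammaln(n_total + 1)
    )
    probs = np.exp(logp)
    p_obs = probs[x == pn][0]
    p = float(probs[probs <= p_obs * (1.0 + _REL_SLACK)].sum())
    return min(p, 1.0)


def alpha_point(t: ContingencyTable2x2) -> float | None:
    """Point estimate alpha = 1 - (Ds*Pn)/(Dn*Ps); None when Dn or Ps is 0."""
    if t.dn == 0 or t.ps == 0:
        return None
    return 1.0 - (t.ds * t.pn) / (t.dn * t.ps)


def _assemble(
    method: str,
    pn: float,
    ps: float,
    div: DivergenceSummary,
    cutoff: float | None,
    notes: list[str],
    fractions: dict[str, float] | None = None,
) -> MktResult:
    table = ContingencyTable2x2(pn=pn, ps=ps, dn=div.dn, ds=div.ds)
    alpha = alpha_point(table)
    if alpha is None:
        notes = notes + ["alpha_undefined"]
    if min(pn + ps, div.dn + div.ds, pn + div.dn, ps + div.ds) == 0:
        notes = notes + ["degenerate_margin"]
    p = fisher_exact_2x2(table)
    return MktResult(
        method=method,
        alpha=alpha,
        p_value=p,
        table=table,
        cutoff=cutoff,
        fractions=fractions,
        notes=notes,
    )


def standard_mkt(daf: DafTable, div: DivergenceSummary) -> MktResult:
    """The original MKT on the pooled spectrum (no frequency filtering)."""
    return _assemble("standard", daf.pn_total, daf.ps_total, div, None, [])


def fww_mkt(
    daf: DafTable, div: DivergenceSummary, cutoff: float = DEFAULT_CUTOFF
) -> MktResult:
    """Fay-Wyckoff-Wu correction: drop all bins with daf < cutoff."""
    if not (0.0 <= cutoff < 1.0):
        raise ValidationError(f"cutoff must be in [0,1), got {cutoff}")
    _, high = daf.split(cutoff)
    if high is None:
        return _assemble("fww", 0, 0, div, cutoff, ["all_bins_below_cutoff"])
    return _assemble("fww", high.pn_total, high.ps_total, div, cutoff, [])


def emkt(
    daf: DafTable, div: DivergenceSummary, cutoff: float = DEFAULT_CUTOFF
) -> MktResult:
    """Extended MKT: partition low-frequency Pn into neutral and weakly
    deleterious parts using the neutral (synonymous) spectrum.

    With L = bins below the cutoff and H = bins at or above it, the expected
    neutral share of pn(L) is pn(H) * ps(L) / ps(H); the weakly deleterious
    count is the (non-negative) remainder. Pn in the 2x2 table is replaced by
    pn_neutral = pn(H) + min(pn(L), expected), while Ps stays the full
    synonymous total. When site totals are known the regime fractions are

        f = m_s * pn_neutral / (m_n * ps_total)   (neutral)
        b = m_s * wd / (m_n * ps_total)           (weakly deleterious)
        d = 1 - f - b                             (strongly deleterious)

    clamped to [0, 1] with a note when clamping occurs.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValidationError(f"cutoff must be in (0,1), got {cutoff}")
    notes: list[str] = []
    low, high = daf.split(cutoff)
    pn_low = low.pn_total if low else 0
    ps_low = low.ps_total if low else 0
    pn_high = high.pn_total if high else 0
    ps_high = high.ps_total if high else 0
    ps_total = daf.ps_total

    if ps_high == 0:
        res = _assemble(
            "emkt", daf.pn_total, ps_total, div, cutoff, ["partition_undefined"]
        )
        return res

    expected_neutral_low = pn_high * ps_low / ps_high
    wd = max(0.0, pn_low - expected_neutral_low)
    if expected_neutral_low > pn_low:
        notes.append("expected_exceeds_observed")
    pn_neutral = pn_high + min(pn_low, expected_neutral_low)

    fractions: dict[str, float] | None = None
    if div.has_site_totals and div.m_n and ps_total > 0:
        f = (div.m_s * pn_neutral) / (div.m_n * ps_total)
        b = (div.m_s * wd) / (div.m_n * ps_total)
        d = 1.0 - f - b
        clamped = {k: min(1.0, max(0.0, v)) for k, v in (("f", f), ("b", b), ("d", d))}
        if any(abs(clamped[k] - v) > 1e-12 for k, v in (("f", f), ("b", b), ("d", d))):
            notes.append("fractions_clamped")
        fractions = clamped
    else:
        notes.append("no_site_totals")

    res = _assemble("emkt", pn_neutral, ps_total, div, cutoff, notes, fractions)
    return res
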