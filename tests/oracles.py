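"""Independent reference implementations used only as test oracles.

Each oracle recomputes a quantity from first principles by a different route
than the package (exact rational arithmetic, brute-force enumeration, grid
search), so agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np
from Bio.Seq import Seq


def fisher_two_sided_exact(pn: int, ps: int, dn: int, ds: int) -> Fraction:
    """Two-sided Fisher exact p by exact rational hypergeometric enumeration."""
    row1, row2 = pn + ps, dn + ds
    col1, col2 = pn + dn, ps + ds
    if min(row1, row2, col1, col2) == 0:
        return Fraction(1)
    n = row1 + row2
    lo, hi = max(0, row1 - col2), min(row1, col1)
    numerators = {x: comb(col1, x) * comb(col2, row1 - x) for x in range(lo, hi + 1)}
    obs = numerators[pn]
    return Fraction(sum(v for v in numerators.values() if v <= obs), comb(n, row1))


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def codon_enumerator(aln):
    """Brute-force per-codon re-derivation of build_tables at full depth.

    Valid only when the subsampling depth equals the number of ingroup
    sequences (no randomness). Every classification is recomputed from the
    genetic code via Biopython translation.
    """
    n_in = len(aln.ingroup)
    seqs = [s for _, s in aln.ingroup]
    out = aln.outgroup[1]
    pn_by_count: Counter = Counter()
    ps_by_count: Counter = Counter()
    dn = ds = 0
    m_n = m_s = 0.0
    excluded = []

    for ci in range(len(out) // 3):
        ing = [s[3 * ci : 3 * ci + 3] for s in seqs]
        og = out[3 * ci : 3 * ci + 3]
        if any(b not in "ACGT" for cod in ing for b in cod):
            excluded.append((ci, "insufficient_depth"))
            continue
        if any(b not in "ACGT" for b in og):
            excluded.append((ci, "unpolarizable"))
            continue
        reason = None
        for k in range(3):
            alleles = {c[k] for c in ing}
            if len(alleles) > 2:
                reason = "multiallelic"
                break
            if len(alleles) == 2 and og[k] not in alleles:
                reason = "unpolarizable"
                break
        if reason:
            excluded.append((ci, reason))
            continue
        events = []
        for k in range(3):
            alleles = {c[k] for c in ing}
            if len(alleles) == 2 or (len(alleles) == 1 and og[k] not in alleles):
                events.append(k)
        if len(events) > 1:
            excluded.append((ci, "multihit"))
            continue
        if _translate(og) == "*":
            excluded.append((ci, "stop"))
            continue
        # Nei-Gojobori fractional site counts on the ancestral (= outgroup) codon
        aa = _translate(og)
        for k in range(3):
            syn = sum(
                1
                for b in "ACGT"
                if b != og[k] and _translate(og[:k] + b + og[k + 1 :]) == aa
            )
            m_s += syn / 3.0
            m_n += (3 - syn) / 3.0
        if not events:
            continue
        k = events[0]
        alleles = {c[k] for c in ing}
        if len(alleles) == 1:  # fixed difference
            derived = next(iter(alleles))
            der_codon = og[:k] + derived + og[k + 1 :]
            if _translate(der_codon) == aa:
                ds += 1
            else:
                dn += 1
        else:
            derived = next(iter(alleles - {og[k]}))
            count = sum(1 for c in ing if c[k] == derived)
            der_codon = og[:k] + derived + og[k + 1 :]
            if _translate(der_codon) == aa:
                ps_by_count[count] += 1
            else:
                pn_by_count[count] += 1

    bins = [
        (i / n_in, pn_by_count.get(i, 0), ps_by_count.get(i, 0))
        for i in range(1, n_in)
    ]
    return {
        "bins": bins,
        "dn": dn,
        "ds": ds,
        "m_n": m_n,
        "m_s": m_s,
        "excluded": sorted(excluded),
    }


def grid_search_exp_sse(x: np.ndarray, y: np.ndarray) -> float:
    """Best exponential-model SSE by profile grid search over the decay rate.

    For fixed c the model a + b*exp(-c*x) is linear in (a, b), so the profile
    SSE(c) is computed in closed form; a coarse log grid is refined by
    bounded scalar minimization around the best grid point.
    """
    from scipy.optimize import minimize_scalar

    def sse_at(c: float) -> float:
        design = np.column_stack([np.ones_like(x), np.exp(-c * x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = design @ coef - y
        return float(r @ r)

    cs = np.logspace(-3, 2, 400)
    sses = np.array([sse_at(c) for c in cs])
    i = int(np.argmin(sses))
    lo, hi = cs[max(0, i - 1)], cs[min(len(cs) - 1, i + 1)]
    res = minimize_scalar(sse_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return min(float(res.fun), float(sses[i]))


def cmh_statistic_textbook(strata: list[np.ndarray]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square (df=1, no continuity correction)."""
    from scipy.stats import chi2

    dev = 0.0
    var = 0.0
    for t in strata:
        n = t.sum()
        r1, c1 = t[0].sum(), t[:, 0].sum()
        r2, c2 = t[1].sum(), t[:, 1].sum()
        dev += t[0, 0] - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n**2 * (n - 1))
    stat = dev**2 / var
    return float(stat), float(chi2.sf(stat, 1))


def breslow_day_textbook(strata: list[np.ndarray]) -> float:
    """Breslow-Day-Tarone statistic from the published formulas."""
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in strata)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in strata)
    psi = num / den
    stat = 0.0
    devs = 0.0
    vars_ = 0.0
    for t in strata:
        a_obs = t[0, 0]
        r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
        # solve psi = a(n - r1 - c1 + a) / ((r1 - a)(c1 - a)) for a
        if abs(psi - 1.0) < 1e-12:
            a = r1 * c1 / n
        else:
            qa = psi - 1.0
            qb = -(psi * (r1 + c1) + (n - r1 - c1))
            qc = psi * r1 * c1
            disc = np.sqrt(max(qb * qb - 4 * qa * qc, 0.0))
            cands = [(-qb - disc) / (2 * qa), (-qb + disc) / (2 * qa)]
            lo, hi = max(0.0, r1 + c1 - n), min(r1, c1)
            a = next(r for r in cands if lo - 1e-9 <= r <= hi + 1e-9)
        v = 1.0 / (
            1.0 / a + 1.0 / (r1 - a) + 1.0 / (c1 - a) + 1.0 / (n - r1 - c1 + a)
        )
        stat += (a_obs - a) ** 2 / v
        devs += a_obs - a
        vars_ += v
    return float(max(stat - devs**2 / vars_, 0.0))
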