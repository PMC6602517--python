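"""From a coding alignment to a DAF spectrum and divergence summary.

The pipeline walks the alignment codon by codon:

1.  Each column is subsampled without replacement to a uniform depth among
    ingroup lines with a determined base (N and '-' are invalid); columns
    with fewer valid lines than the depth are discarded.
2.  Each column is polarized against the single outgroup base: a segregating
    allele matching the outgroup is ancestral, the other derived; an ingroup
    monomorphic base differing from the outgroup is a fixed difference.
3.  A single-nucleotide change within a codon is synonymous (neutral class)
    when ancestral and derived codons encode the same amino acid under the
    standard nuclear genetic code, otherwise nonsynonymous (selected class).
    Codons carrying more than one segregating or divergent position are
    excluded ("multihit"), as are codons whose ancestral state is a stop
    codon or cannot be polarized.
4.  Site totals m_n / m_s are Nei-Gojobori fractional counts on the
    ancestral codon of every retained codon: each codon position contributes
    (number of synonymous one-step mutations)/3 to m_s and the complement to
    m_n, so m_n + m_s = 3 x retained codons.

Subsampling uses one integer seed with a counter-mode stream per alignment
column, so per-column draws are independent of processing order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .types import Alignment, DafBin, DafTable, DivergenceSummary, ValidationError

_BASES = "ACGT"

# Standard nuclear genetic code (NCBI table 1); stop codons translate to "*".
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

SELECTED = "selected"
NEUTRAL = "neutral"

#: constraint order used when transcript frames disagree (most constrained wins)
_CLASS_RANK = {SELECTED: 1, NEUTRAL: 0}


@dataclass
class SiteObservation:
    """Per-column outcome retained in the build log."""

    position: int
    codon_index: int
    within_codon_pos: int
    allele_counts: dict[str, int]
    outgroup_base: str | None
    site_class: str | None = None
    exclusion_reason: str | None = None


@dataclass
class BuildResult:
    """Output of :func:`build_tables` plus the per-codon exclusion log."""

    daf: DafTable
    div: DivergenceSummary
    depth: int
    n_codons_retained: int
    excluded_codons: list[tuple[int, str]] = field(default_factory=list)
    observations: list[SiteObservation] = field(default_factory=list)

    @property
    def exclusion_counts(self) -> dict[str, int]:
        return dict(Counter(reason for _, reason in self.excluded_codons))


def subsample_columns(
    aln: Alignment, depth: int, seed: int
) -> list[dict[str, int] | None]:
    """Subsample every alignment column to a fixed depth.

    Returns, per column, a base->count mapping summing to ``depth``, or
    ``None`` when fewer than ``depth`` ingroup lines carry a valid base
    (the "insufficient_depth" exclusion). Draws are without replacement from
    a per-column seeded stream; the valid bases are sorted before drawing so
    the result does not depend on the order of the ingroup sequences.
    """
    n_in = len(aln.ingroup)
    if not (2 <= depth <= n_in):
        raise ValidationError(f"depth must be in [2, {n_in}], got {depth}")
    out: list[dict[str, int] | None] = []
    for col in range(aln.length):
        bases = sorted(
            seq[col] for _, seq in aln.ingroup if seq[col] in _BASES
        )
        if len(bases) < depth:
            out.append(None)
        elif len(bases) == depth:
            out.append(dict(Counter(bases)))
        else:
            rng = np.random.default_rng([seed, col])
            picked = rng.choice(len(bases), size=depth, replace=False)
            out.append(dict(Counter(bases[i] for i in picked)))
    return out


def classify_site(ancestral_codon: str, derived_codon: str) -> str:
    """Classify a single-nucleotide codon change as neutral or selected.

    Neutral iff both codons encode the same amino acid under the standard
    code. The caller guarantees a single differing position and a non-stop
    ancestral codon.
    """
    diffs = sum(a != b for a, b in zip(ancestral_codon, derived_codon))
    if diffs != 1:
        raise ValidationError(
            f"expected exactly one difference between {ancestral_codon} and "
            f"{derived_codon}, found {diffs}"
        )
    anc_aa = GENETIC_CODE[ancestral_codon]
    der_aa = GENETIC_CODE[derived_codon]
    return NEUTRAL if anc_aa == der_aa else SELECTED


def resolve_overlapping_classes(classes: list[str]) -> str:
    """Most-constrained class wins when overlapping frames disagree."""
    if not classes:
        raise ValidationError("no class proposals to resolve")
    for c in classes:
        if c not in _CLASS_RANK:
            raise ValidationError(f"unknown site class {c!r}")
    return max(classes, key=lambda c: _CLASS_RANK[c])


@dataclass
class PolarizedSite:
    """Outcome of polarizing one subsampled column against the outgroup."""

    kind: str  # polymorphic | fixed_difference | monomorphic_conserved | excluded
    ancestral: str | None = None
    derived: str | None = None
    derived_count: int | None = None
    reason: str | None = None


def polarize(allele_counts: dict[str, int], outgroup_base: str | None) -> PolarizedSite:
    """Assign ancestral/derived status using the outgroup base.

    Multiallelic ingroup columns are excluded ("multiallelic"); a missing
    outgroup base, or one matching neither segregating allele, excludes the
    column as "unpolarizable".
    """
    alleles = sorted(a for a, c in allele_counts.items() if c > 0)
    if len(alleles) > 2:
        return PolarizedSite(kind="excluded", reason="multiallelic")
    if outgroup_base is None or outgroup_base not in _BASES:
        return PolarizedSite(kind="excluded", reason="unpolarizable")
    if len(alleles) == 1:
        a = alleles[0]
        if a == outgroup_base:
            return PolarizedSite(kind="monomorphic_conserved", ancestral=a)
        return PolarizedSite(kind="fixed_difference", ancestral=outgroup_base, derived=a)
    a1, a2 = alleles
    if outgroup_base == a1:
        anc, der = a1, a2
    elif outgroup_base == a2:
        anc, der = a2, a1
    else:
        return PolarizedSite(kind="excluded", reason="unpolarizable")
    return PolarizedSite(
        kind="polymorphic",
        ancestral=anc,
        derived=der,
        derived_count=allele_counts[der],
    )


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Nei-Gojobori fractional (m_n, m_s) contribution of one codon.

    Each position contributes s/3 to m_s, where s is the number of the three
    possible point mutations at that position that preserve the amino acid;
    changes to or from a stop codon count as nonsynonymous. The two values
    always sum to 3.
    """
    aa = GENETIC_CODE[codon]
    ms = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa and aa != "*":
                syn += 1
        ms += syn / 3.0
    return 3.0 - ms, ms


def count_site_totals(ancestral_codons: list[str]) -> tuple[float, float]:
    """Sum Nei-Gojobori site counts over the retained ancestral codons."""
    m_n = m_s = 0.0
    for codon in ancestral_codons:
        n, s = codon_site_counts(codon)
        m_n += n
        m_s += s
    return m_n, m_s


def default_depth(aln: Alignment, coverage: float = 0.9) -> int:
    """Largest depth n >= 2 such that >= ``coverage`` of columns have n valid lines."""
    n_in = len(aln.ingroup)
    arr = np.array([list(seq) for _, seq in aln.ingroup])
    valid = np.isin(arr, list(_BASES)).sum(axis=0)
    for depth in range(n_in, 1, -1):
        if np.mean(valid >= depth) >= coverage:
            return depth
    return 2


def build_tables(
    aln: Alignment,
    depth: int | None = None,
    seed: int = 0,
    keep_observations: bool = False,
) -> BuildResult:
    """Run the full codon pipeline and assemble the MKT input tables.

    The DAF table has bins at frequencies i/depth for i = 1..depth-1
    (zero-count bins included); the divergence summary carries dn/ds from
    fixed differences and Nei-Gojobori m_n/m_s over retained codons. Every
    excluded codon is logged with its reason.
    """
    if depth is None:
        depth = default_depth(aln)
    columns = subsample_columns(aln, depth, seed)
    out_seq = aln.outgroup[1]

    pn_by_count = np.zeros(depth, dtype=int)  # index = derived count 1..depth-1
    ps_by_count = np.zeros(depth, dtype=int)
    dn = ds = 0
    ancestral_codons: list[str] = []
    excluded: list[tuple[int, str]] = []
    observations: list[SiteObservation] = []

    for ci in range(aln.n_codons):
        cols = [3 * ci + k for k in range(3)]
        counts3 = [columns[c] for c in cols]
        outg3 = [out_seq[c] if out_seq[c] in _BASES else None for c in cols]

        def _log(reason: str | None, classes: list[str | None] | None = None) -> None:
            if not keep_observations:
                return
            for k, c in enumerate(cols):
                observations.append(
                    SiteObservation(
                        position=c,
                        codon_index=ci,
                        within_codon_pos=k,
                        allele_counts=counts3[k] or {},
                        outgroup_base=outg3[k],
                        site_class="excluded" if reason else (classes or [None] * 3)[k],
                        exclusion_reason=reason,
                    )
                )

        if any(c is None for c in counts3):
            excluded.append((ci, "insufficient_depth"))
            _log("insufficient_depth")
            continue
        if any(b is None for b in outg3):
            excluded.append((ci, "unpolarizable"))
            _log("unpolarizable")
            continue

        pol3 = [polarize(counts3[k], outg3[k]) for k in range(3)]
        bad = next((p for p in pol3 if p.kind == "excluded"), None)
        if bad is not None:
            excluded.append((ci, bad.reason or "excluded"))
            _log(bad.reason)
            continue

        events = [k for k, p in enumerate(pol3) if p.kind != "monomorphic_conserved"]
        if len(events) > 1:
            excluded.append((ci, "multihit"))
            _log("multihit")
            continue

        # With <=1 event the ancestral codon is the outgroup codon: every
        # conserved position matches the outgroup and the focal position's
        # ancestral allele is the outgroup base by the polarization rule.
        anc_codon = "".join(outg3)  # type: ignore[arg-type]
        if GENETIC_CODE[anc_codon] == "*":
            excluded.append((ci, "stop"))
            _log("stop")
            continue

        ancestral_codons.append(anc_codon)
        if not events:
            _log(None)
            continue

        k = events[0]
        p = pol3[k]
        der_codon = anc_codon[:k] + p.derived + anc_codon[k + 1 :]
        site_class = classify_site(anc_codon, der_codon)
        classes: list[str | None] = [None, None, None]
        classes[k] = site_class
        _log(None, classes)
        if p.kind == "fixed_difference":
            if site_class == SELECTED:
                dn += 1
            else:
                ds += 1
        else:  # polymorphic
            d = p.derived_count
            assert d is not None and 1 <= d <= depth - 1
            if site_class == SELECTED:
                pn_by_count[d] += 1
            else:
                ps_by_count[d] += 1

    if not ancestral_codons:
        raise ValidationError("empty_after_filters: no codons survive filtering")

    m_n, m_s = count_site_totals(ancestral_codons)
    bins = [
        DafBin(i / depth, int(pn_by_count[i]), int(ps_by_count[i]))
        for i in range(1, depth)
    ]
    daf = DafTable(n_sample=depth, bins=bins)
    div = DivergenceSummary(dn=dn, ds=ds, m_n=m_n, m_s=m_s)
    return BuildResult(
        daf=daf,
        div=div,
        depth=depth,
        n_codons_retained=len(ancestral_codons),
        excluded_codons=excluded,
        observations=observations,
    )
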