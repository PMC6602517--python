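"""Core domain containers shared across the toolkit.

Every container validates its invariants on construction so that readers,
simulators and estimators can assume well-formed data downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass(frozen=True)
class DafBin:
    """One derived-allele-frequency class: frequency and per-class counts."""

    daf: float
    pn: int
    ps: int


@dataclass
class DafTable:
    """Site-frequency spectrum of segregating variants at fixed sample depth.

    Parameters
    ----------
    n_sample
        Number of chromosomes sampled (the depth at which derived allele
        counts were taken).
    bins
        Ordered ``DafBin`` records. Frequencies must be strictly increasing
        and lie in the open interval (0, 1): monomorphic and fixed classes
        belong in :class:`DivergenceSummary`, not here.
    """

    n_sample: int
    bins: list[DafBin]

    def __post_init__(self) -> None:
        self.bins = [b if isinstance(b, DafBin) else DafBin(*b) for b in self.bins]
        if self.n_sample < 2:
            raise ValidationError("n_sample must be >= 2")
        if not self.bins:
            raise ValidationError("DafTable requires at least one bin")
        prev = 0.0
        for b in self.bins:
            if not (0.0 < b.daf < 1.0):
                raise ValidationError(
                    f"daf={b.daf} outside open interval (0,1); fixed variants "
                    "are divergence, not polymorphism"
                )
            if b.daf <= prev:
                raise ValidationError("daf values must be strictly increasing")
            if b.pn < 0 or b.ps < 0:
                raise ValidationError("bin counts must be non-negative")
            if b.pn != int(b.pn) or b.ps != int(b.ps):
                raise ValidationError("bin counts must be integers")
            prev = b.daf

    @property
    def pn_total(self) -> int:
        return sum(b.pn for b in self.bins)

    @property
    def ps_total(self) -> int:
        return sum(b.ps for b in self.bins)

    def split(self, cutoff: float) -> tuple["DafTable | None", "DafTable | None"]:
        """Partition bins into (daf < cutoff, daf >= cutoff); either may be None."""
        low = [b for b in self.bins if b.daf < cutoff]
        high = [b for b in self.bins if b.daf >= cutoff]
        return (
            DafTable(self.n_sample, low) if low else None,
            DafTable(self.n_sample, high) if high else None,
        )


@dataclass
class DivergenceSummary:
    """Fixed differences to the outgroup plus analyzed site totals.

    ``m_n``/``m_s`` (numbers of selected/neutral sites analyzed) may be
    ``None`` when unknown; selection-regime fractions then cannot be computed.
    """

    dn: int
    ds: int
    m_n: float | None = None
    m_s: float | None = None

    def __post_init__(self) -> None:
        if self.dn < 0 or self.ds < 0:
            raise ValidationError("divergence counts must be non-negative")
        for m in (self.m_n, self.m_s):
            if m is not None and m < 0:
                raise ValidationError("site totals must be non-negative")
        if self.m_n is not None and self.m_n > 0 and self.dn > self.m_n:
            raise ValidationError("dn exceeds m_n")
        if self.m_s is not None and self.m_s > 0 and self.ds > self.m_s:
            raise ValidationError("ds exceeds m_s")

    @property
    def has_site_totals(self) -> bool:
        return self.m_n is not None and self.m_s is not None


@dataclass
class GeneRecord:
    """One gene's polymorphism spectrum, divergence summary and metadata."""

    gene_id: str
    daf: DafTable
    div: DivergenceSummary
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")


_VALID_BASES = set("ACGTN-")


@dataclass
class Alignment:
    """Aligned same-species coding sequences plus one outgroup orthologue.

    Sequences are upper-cased on construction; the alphabet is restricted to
    A/C/G/T plus N and the gap character, lengths must match and be a
    multiple of three (the input is assumed CDS-trimmed, frame starting at
    column 0).
    """

    ingroup: list[tuple[str, str]]
    outgroup: tuple[str, str]

    def __post_init__(self) -> None:
        self.ingroup = [(i, s.upper()) for i, s in self.ingroup]
        self.outgroup = (self.outgroup[0], self.outgroup[1].upper())
        if len(self.ingroup) < 2:
            raise ValidationError("need >= 2 ingroup sequences")
        ids = [i for i, _ in self.ingroup] + [self.outgroup[0]]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate record id(s): {sorted(dup)}")
        length = len(self.outgroup[1])
        for rid, seq in list(self.ingroup) + [self.outgroup]:
            if len(seq) != length:
                raise ValidationError(
                    f"sequence {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValidationError(f"invalid characters in {rid!r}: {sorted(bad)}")
        if length % 3 != 0:
            raise ValidationError(f"alignment length {length} not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.outgroup[1])

    @property
    def n_codons(self) -> int:
        return self.length // 3


@dataclass
class ContingencyTable2x2:
    """MKT 2x2 table: polymorphism (pn, ps) vs divergence (dn, ds)."""

    pn: float
    ps: float
    dn: float
    ds: float

    def __post_init__(self) -> None:
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValidationError("contingency counts must be non-negative")


@dataclass
class MktResult:
    """Outcome of one MKT variant on one (DafTable, DivergenceSummary) pair.

    ``alpha`` and ``p_value`` are ``None`` when undefined (a diagnostic tag
    in ``notes`` says why). ``fractions`` holds the selection-regime split
    {f: neutral, b: weakly deleterious, d: strongly deleterious} when site
    totals were available (extended MKT only).
    """

    method: str
    alpha: float | None
    p_value: float | None
    table: ContingencyTable2x2
    cutoff: float | None = None
    fractions: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "method": self.method,
            "alpha": self.alpha,
            "p_value": self.p_value,
            "cutoff": self.cutoff,
            "table": {
                "pn": self.table.pn,
                "ps": self.table.ps,
                "dn": self.table.dn,
                "ds": self.table.ds,
            },
            "notes": list(self.notes),
        }
        if self.fractions is not None:
            d["fractions"] = dict(self.fractions)
        return d


@dataclass
class AlphaTrajectory:
    """Per-frequency-class alpha(x) values for the asymptotic MKT.

    ``points`` is an ordered list of ``(x, alpha_x)`` with ``alpha_x`` set to
    ``None`` where undefined; ``undefined_reasons`` maps such x to a tag.
    """

    points: list[tuple[float, float | None]]
    undefined_reasons: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev = 0.0
        for x, _ in self.points:
            if not (0.0 < x < 1.0):
                raise ValidationError("trajectory x values must lie in (0,1)")
            if x <= prev:
                raise ValidationError("trajectory x values must be increasing")
            prev = x

    @property
    def defined_points(self) -> list[tuple[float, float]]:
        return [(x, a) for x, a in self.points if a is not None]


@dataclass
class AsymptoticFit:
    """Fitted alpha(x) model and its extrapolated asymptote at x=1."""

    model: str  # "exponential" | "linear"
    a: float
    b: float
    c: float | None
    alpha_asymptote: float
    ci_low: float | None
    ci_high: float | None
    x_interval: tuple[float, float]
    converged: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "alpha_asymptote": self.alpha_asymptote,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "x_interval": list(self.x_interval),
            "converged": self.converged,
            "notes": list(self.notes),
        }


@dataclass
class CmhResult:
    """Stratified 2x2 test across genes (strata)."""

    statistic: float
    df: int
    p_value: float
    k_strata: int
    variant: str  # "common-association" | "heterogeneity"

    def to_dict(self) -> dict[str, Any]:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "k_strata": self.k_strata,
            "variant": self.variant,
        }


@dataclass
class BootstrapSummary:
    """Summary of one group's bootstrap sampling distribution of alpha."""

    label: str
    replicate_alphas: list[float]
    n_reps: int
    n_dropped: int
    sample_size: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    flagged: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "n_reps": self.n_reps,
            "n_dropped": self.n_dropped,
            "sample_size": self.sample_size,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "flagged": self.flagged,
        }


@dataclass
class BootstrapComparison:
    """Bootstrap comparison of alpha between two gene groups."""

    group_a: BootstrapSummary
    group_b: BootstrapSummary
    diff_mean: float
    diff_ci_low: float
    diff_ci_high: float
    method: str
    cutoff: float | None
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "group_a": self.group_a.to_dict(),
            "group_b": self.group_b.to_dict(),
            "diff_mean": self.diff_mean,
            "diff_ci_low": self.diff_ci_low,
            "diff_ci_high": self.diff_ci_high,
            "method": self.method,
            "cutoff": self.cutoff,
            "seed": self.seed,
        }


def metadata_value(meta: Mapping[str, Any], key: str) -> Any:
    if key not in meta:
        raise KeyError(key)
    return meta[key]
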