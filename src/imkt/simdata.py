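"""Seeded generators for every input the toolkit consumes.

The gene simulator draws site-frequency spectra from the standard-neutral
expectation with Poisson noise rather than from a coalescent: the expected
number of neutral variants at derived count i in a sample of n chromosomes
is theta_s * m_s / i (Watterson), and the selected class mixes a neutral
component (fraction f of selected sites), a weakly deleterious component
with a low-frequency-skewed spectrum proportional to 1/i^(1+weak_skew)
(same total mass as the neutral shape, no divergence contribution), and a
strongly deleterious component (fraction d) contributing neither
polymorphism nor divergence. Neutral divergence is Poisson(ds_mean) and
selected divergence Poisson(ds_mean * (m_n/m_s) * f / (1 - alpha_true)), so
the expected standard-MKT alpha on b = 0 data equals alpha_true by
construction. This gives calibrated ground truth for estimator tests at the
cost of genealogical realism (no linkage, demography or sampling noise in
the frequencies themselves).

``make_toy_alignment`` builds tiny coding alignments with planted events
(synonymous/nonsynonymous polymorphisms and fixed differences, plus the
exclusion cases) together with the exact tables the spectrum pipeline must
produce from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

from . import codon_spectrum
from .types import (
    Alignment,
    DafBin,
    DafTable,
    DivergenceSummary,
    GeneRecord,
    ValidationError,
)


@dataclass
class RegimeParams:
    """Generative parameters for one gene under mixed selection regimes.

    f, b and d are the fractions of selected sites evolving neutrally,
    under weak purifying selection and under strong purifying selection;
    they must sum to 1. ``alpha_true`` is the fraction of selected-class
    divergence driven by positive selection. ``theta_s`` scales the expected
    neutral spectrum (per neutral site), ``ds_mean`` the expected neutral
    divergence count.
    """

    n_sample: int = 20
    m_n: float = 750.0
    m_s: float = 250.0
    theta_s: float = 0.02
    f: float = 0.7
    b: float = 0.0
    d: float = 0.3
    weak_skew: float = 1.0
    alpha_true: float = 0.0
    ds_mean: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.f + self.b + self.d - 1.0) > 1e-9:
            raise ValidationError("regime fractions f+b+d must sum to 1")
        for v in (self.f, self.b, self.d):
            if not (0.0 <= v <= 1.0):
                raise ValidationError("regime fractions must lie in [0,1]")
        if not (0.0 <= self.alpha_true < 1.0):
            raise ValidationError("alpha_true must lie in [0,1)")


def expected_spectra(p: RegimeParams) -> tuple[np.ndarray, np.ndarray]:
    """Expected (lambda_pn, lambda_ps) per derived count i = 1..n-1."""
    i = np.arange(1, p.n_sample)
    neutral_shape = p.theta_s * p.m_s / i  # expected neutral counts
    skew_raw = 1.0 / i ** (1.0 + p.weak_skew)
    skew_shape = skew_raw * neutral_shape.sum() / skew_raw.sum()
    ratio = p.m_n / p.m_s
    lam_pn = ratio * (p.f * neutral_shape + p.b * skew_shape)
    return lam_pn, neutral_shape


def expected_divergence(p: RegimeParams) -> tuple[float, float]:
    """Expected (dn, ds) under the generative model."""
    dn = p.ds_mean * (p.m_n / p.m_s) * p.f / (1.0 - p.alpha_true)
    return dn, p.ds_mean


def simulate_gene(p: RegimeParams, gene_id: str = "gene", rng=None) -> GeneRecord:
    """Draw one gene: Poisson spectra around the regime expectations."""
    if rng is None:
        rng = np.random.default_rng(p.seed)
    lam_pn, lam_ps = expected_spectra(p)
    pn = rng.poisson(lam_pn)
    ps = rng.poisson(lam_ps)
    dn_mean, ds_mean = expected_divergence(p)
    dn = int(rng.poisson(dn_mean))
    ds = int(rng.poisson(ds_mean))
    bins = [
        DafBin(i / p.n_sample, int(pn[i - 1]), int(ps[i - 1]))
        for i in range(1, p.n_sample)
    ]
    daf = DafTable(n_sample=p.n_sample, bins=bins)
    div = DivergenceSummary(
        dn=min(dn, int(p.m_n)), ds=min(ds, int(p.m_s)), m_n=p.m_n, m_s=p.m_s
    )
    return GeneRecord(
        gene_id=gene_id,
        daf=daf,
        div=div,
        metadata={"generative_params": {k: v for k, v in asdict(p).items() if k != "seed"}},
    )


_CHROMOSOMES = ("2L", "2R", "3L", "3R", "X")


def simulate_cohort(
    k: int,
    params: RegimeParams,
    seed: int | None = None,
    prefix: str = "g",
    recombination_range: tuple[float, float] = (0.0, 12.0),
) -> list[GeneRecord]:
    """Simulate k genes with chromosome and recombination-rate metadata.

    Recombination rates are drawn uniformly from ``recombination_range``
    (cM/Mb) so that threshold filters have both sides populated.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    genes = []
    for j in range(k):
        g = simulate_gene(params, gene_id=f"{prefix}{j:04d}", rng=rng)
        g.metadata["chromosome"] = str(rng.choice(_CHROMOSOMES))
        g.metadata["recombination_rate"] = float(
            np.round(rng.uniform(*recombination_range), 3)
        )
        genes.append(g)
    return genes


# --- toy alignments with planted events ------------------------------------

#: per event type: (ancestral codon, focal position, derived base). Ancestral
#: codons are chosen so the planted change has the advertised class under the
#: standard code (TTT->TTC Phe/Phe synonymous; TTT->TTA Phe/Leu nonsynonymous).
_EVENT_TEMPLATES: dict[str, tuple[str, int, str]] = {
    "syn-poly": ("TTT", 2, "C"),
    "nonsyn-poly": ("TTT", 2, "A"),
    "syn-fixed": ("TTT", 2, "C"),
    "nonsyn-fixed": ("TTT", 2, "A"),
    "multiallelic": ("TTT", 2, "C"),
    "unpolarizable": ("TTT", 2, "C"),
    "missing-N": ("TTT", 2, "N"),
    "multihit": ("TTT", 0, "C"),
    "stop": ("TGA", 2, "G"),
}

#: codon used at non-event positions (Gly; conserved across all lines)
_FILLER_CODON = "GGC"


@dataclass
class ToyEvent:
    """One planted event: codon index, type, and derived-allele count."""

    codon_index: int
    kind: str
    derived_count: int = 1


@dataclass
class ToyAlignmentResult:
    """Alignment plus the tables build_tables must produce from it."""

    alignment: Alignment
    expected_daf: DafTable
    expected_div: DivergenceSummary
    expected_exclusions: list[tuple[int, str]] = field(default_factory=list)


def make_toy_alignment(
    events: Sequence[ToyEvent | tuple],
    n_codons: int = 10,
    n_ingroup: int = 4,
) -> ToyAlignmentResult:
    """Build an alignment in which the spectrum pipeline provably yields the
    planted counts (at depth = number of ingroup sequences).

    Also returns the expected DAF table, divergence summary and exclusion
    log, computed from the construction itself.
    """
    evs = [e if isinstance(e, ToyEvent) else ToyEvent(*e) for e in events]
    used = set()
    for e in evs:
        if e.kind not in _EVENT_TEMPLATES:
            raise ValidationError(f"unknown event kind {e.kind!r}")
        if not (0 <= e.codon_index < n_codons):
            raise ValidationError(f"codon_index {e.codon_index} out of range")
        if e.codon_index in used:
            raise ValidationError(f"conflicting events on codon {e.codon_index}")
        if "poly" in e.kind and not (1 <= e.derived_count <= n_ingroup - 1):
            raise ValidationError("derived_count must be in [1, n_ingroup-1]")
        used.add(e.codon_index)

    # start everyone (ingroup + outgroup) identical
    codons_out = [_FILLER_CODON] * n_codons
    codons_in = [[_FILLER_CODON] * n_codons for _ in range(n_ingroup)]

    dn = ds = 0
    pn_by_count = np.zeros(n_ingroup, dtype=int)
    ps_by_count = np.zeros(n_ingroup, dtype=int)
    exclusions: list[tuple[int, str]] = []
    excluded_codons: set[int] = set()

    for e in evs:
        anc, pos, der = _EVENT_TEMPLATES[e.kind]
        codons_out[e.codon_index] = anc

        def _set(line: int, base: str) -> None:
            c = codons_in[line][e.codon_index]
            codons_in[line][e.codon_index] = c[:pos] + base + c[pos + 1 :]

        for line in range(n_ingroup):
            codons_in[line][e.codon_index] = anc

        if e.kind in ("syn-poly", "nonsyn-poly"):
            for line in range(e.derived_count):
                _set(line, der)
            cls = "ps" if e.kind == "syn-poly" else "pn"
            if cls == "ps":
                ps_by_count[e.derived_count] += 1
            else:
                pn_by_count[e.derived_count] += 1
        elif e.kind in ("syn-fixed", "nonsyn-fixed"):
            for line in range(n_ingroup):
                _set(line, der)
            if e.kind == "syn-fixed":
                ds += 1
            else:
                dn += 1
        elif e.kind == "multiallelic":
            if n_ingroup < 3:
                raise ValidationError("multiallelic event needs >= 3 ingroup lines")
            _set(0, "C")
            _set(1, "A")
            exclusions.append((e.codon_index, "multiallelic"))
            excluded_codons.add(e.codon_index)
        elif e.kind == "unpolarizable":
            # ingroup segregates C/A while the outgroup keeps T at the site
            half = max(1, n_ingroup // 2)
            for line in range(n_ingroup):
                _set(line, "C" if line < half else "A")
            exclusions.append((e.codon_index, "unpolarizable"))
            excluded_codons.add(e.codon_index)
        elif e.kind == "missing-N":
            _set(0, "N")
            exclusions.append((e.codon_index, "insufficient_depth"))
            excluded_codons.add(e.codon_index)
        elif e.kind == "multihit":
            # two segregating positions within one codon
            _set(0, der)
            c = codons_in[1][e.codon_index]
            codons_in[1][e.codon_index] = c[:2] + "A" + c[3:]
            exclusions.append((e.codon_index, "multihit"))
            excluded_codons.add(e.codon_index)
        elif e.kind == "stop":
            # ancestral codon is a stop (TGA); one line carries a change
            _set(0, der)
            exclusions.append((e.codon_index, "stop"))
            excluded_codons.add(e.codon_index)

    ingroup = [
        (f"ing{j}", "".join(codons_in[j])) for j in range(n_ingroup)
    ]
    outgroup = ("outg", "".join(codons_out))
    aln = Alignment(ingroup=ingroup, outgroup=outgroup)

    retained = [codons_out[i] for i in range(n_codons) if i not in excluded_codons]
    if not retained:
        raise ValidationError("toy spec leaves no retained codons")
    m_n, m_s = codon_spectrum.count_site_totals(retained)
    bins = [
        DafBin(i / n_ingroup, int(pn_by_count[i]), int(ps_by_count[i]))
        for i in range(1, n_ingroup)
    ]
    return ToyAlignmentResult(
        alignment=aln,
        expected_daf=DafTable(n_sample=n_ingroup, bins=bins),
        expected_div=DivergenceSummary(dn=dn, ds=ds, m_n=m_n, m_s=m_s),
        expected_exclusions=sorted(exclusions),
    )


# --- presets for the CLI ----------------------------------------------------

PRESETS: dict[str, dict[str, Any]] = {
    "neutral": {"f": 1.0, "b": 0.0, "d": 0.0, "alpha_true": 0.0},
    "adaptive": {"f": 0.7, "b": 0.0, "d": 0.3, "alpha_true": 0.5},
    "deleterious": {"f": 0.5, "b": 0.3, "d": 0.2, "alpha_true": 0.3},
}


def preset_params(name: str, seed: int = 0, **overrides: Any) -> RegimeParams:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return RegimeParams(seed=seed, **kwargs)


def figure2_style_groups(
    seed: int = 0,
    k_high: int = 475,
    k_genome: int = 2000,
    alpha_high: float = 0.6,
    alpha_genome: float = 0.44,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Two cohorts mimicking a high-recombination subset vs genome-wide set.

    The high-recombination group gets rates above 7 cM/Mb and the higher
    true adaptation rate; the genome-wide group spans the full rate range.
    """
    p_high = RegimeParams(f=0.7, b=0.0, d=0.3, alpha_true=alpha_high, seed=seed)
    p_gen = RegimeParams(f=0.7, b=0.0, d=0.3, alpha_true=alpha_genome, seed=seed)
    high = simulate_cohort(
        k_high, p_high, seed=_child(seed, 1), prefix="hr", recombination_range=(7.01, 12.0)
    )
    genome = simulate_cohort(
        k_genome, p_gen, seed=_child(seed, 2), prefix="gw", recombination_range=(0.0, 12.0)
    )
    return high, genome


def _child(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))
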