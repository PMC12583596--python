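"""Parent-of-origin assignment and meiotic timing of duplications.

Allele-balance phasing from trio SNPs.  For an event altering dosage over an
interval (duplication: CN=3; deletion: CN=1 / hemizygous), sites where the
parental genotypes make the dosage change attributable to one parent are
"informative".  Two steps:

* **origin** — at sites where the parents are opposite homozygotes, the
  proband's alt-allele read fraction identifies the parent whose
  contribution changed.  At a CN=3 duplication the duplicating parent's
  allele is present in 2 of 3 copies (fraction 2/3 vs 1/3); at a hemizygous
  deletion the surviving allele names the non-deleted parent.
* **timing** (maternal duplications only) — at sites where the mother is
  heterozygous and the father homozygous, a proband minor-allele fraction
  near 1/3 means both maternal homologs are present (heterologous — the
  duplication predates homolog separation at meiosis I), while fractions
  near 0 or 2/3 mean a doubled single homolog (homologous — meiosis II,
  before sister-chromatid separation).

At each step the winning class must hold a fraction of informative sites
> 0.9 and be supported by >= 3 SNPs; otherwise the call is ambiguous.
Paternal duplications get no timing call: paternal duplications can also
arise premeiotically throughout spermatogenesis, so meiotic staging is not
identifiable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import AnalysisParams, Genotype, SNPGenotypeRow

MATERNAL = "maternal"
PATERNAL = "paternal"
UNKNOWN = "unknown"


class Timing(str, enum.Enum):
    MI = "MI"
    MII = "MII"
    AMBIGUOUS = "ambiguous"
    NA = "NA"


class SiteSupport(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    HETEROLOGOUS_MI = "heterologous_MI"
    HOMOLOGOUS_MII = "homologous_MII"


@dataclass(frozen=True)
class InformativeSite:
    site: SNPGenotypeRow
    step: str  # "origin" | "timing"
    support: SiteSupport
    minor_fraction: float


@dataclass(frozen=True)
class OriginTimingCall:
    event_id: str
    origin: str  # maternal | paternal | unknown
    timing: Timing
    n_support_maternal: int = 0
    n_support_paternal: int = 0
    n_support_mi: int = 0
    n_support_mii: int = 0


def _alt_fraction(depths: tuple[int, int]) -> float | None:
    rd, ad = depths
    total = rd + ad
    return ad / total if total > 0 else None


def _near(x: float, target: float, tol: float) -> bool:
    return abs(x - target) <= tol


def collect_informative_sites(
    snp_rows: list[SNPGenotypeRow],
    event_kind: str,
    region: tuple[str, int, int],
    params: AnalysisParams | None = None,
) -> list[InformativeSite]:
    """Extract origin- and timing-informative sites inside ``region``.

    ``event_kind`` is "duplication" (CN=3 over the region) or "deletion"
    (hemizygous).  Sites with missing genotypes or zero proband depth are
    skipped.
    """
    params = params or AnalysisParams()
    tol = params.af_tolerance
    chrom, start, end = region
    out: list[InformativeSite] = []
    for row in snp_rows:
        if row.chrom != chrom or not start <= row.pos < end:
            continue
        gt_f = row.genotypes.get("father", Genotype.MISSING)
        gt_m = row.genotypes.get("mother", Genotype.MISSING)
        if Genotype.MISSING in (gt_f, gt_m):
            continue
        f = _alt_fraction(row.depths.get("proband", (0, 0)))
        if f is None:
            continue

        # origin step: parents opposite homozygotes
        if {gt_f, gt_m} == {Genotype.HOM_REF, Genotype.HOM_ALT}:
            mother_allele_frac = f if gt_m == Genotype.HOM_ALT else 1.0 - f
            support: SiteSupport | None = None
            if event_kind == "duplication":
                if _near(mother_allele_frac, 2 / 3, tol):
                    support = SiteSupport.MATERNAL
                elif _near(mother_allele_frac, 1 / 3, tol):
                    support = SiteSupport.PATERNAL
            else:  # deletion: surviving allele names the retained parent
                if mother_allele_frac <= tol:
                    support = SiteSupport.MATERNAL
                elif mother_allele_frac >= 1.0 - tol:
                    support = SiteSupport.PATERNAL
            if support is not None:
                out.append(InformativeSite(row, "origin", support, min(f, 1 - f)))

        # timing step: mother heterozygous, father homozygous (duplications)
        if (
            event_kind == "duplication"
            and gt_m == Genotype.HET
            and gt_f in (Genotype.HOM_REF, Genotype.HOM_ALT)
        ):
            # fraction of the maternal-specific allele (the one father lacks)
            g = f if gt_f == Genotype.HOM_REF else 1.0 - f
            support = None
            if _near(g, 1 / 3, tol):
                support = SiteSupport.HETEROLOGOUS_MI
            elif g <= tol or _near(g, 2 / 3, tol):
                support = SiteSupport.HOMOLOGOUS_MII
            if support is not None:
                out.append(InformativeSite(row, "timing", support, min(g, 1 - g)))
    return out


def decide(
    count_a: int, count_b: int, params: AnalysisParams | None = None
) -> str:
    """Binary class decision: "A", "B" or "ambiguous".

    The winner's fraction of informative sites must exceed 0.9 (strict) and
    the winner must have at least 3 supporting SNPs.
    """
    params = params or AnalysisParams()
    total = count_a + count_b
    if total == 0:
        return "ambiguous"
    for name, count in (("A", count_a), ("B", count_b)):
        if count / total > params.timing_frac and count >= params.timing_min_snps:
            return name
    return "ambiguous"


def call_origin_and_timing(
    event_id: str,
    event_kind: str,
    region: tuple[str, int, int],
    snp_rows: list[SNPGenotypeRow],
    params: AnalysisParams | None = None,
) -> OriginTimingCall:
    """Two-step call: parent of origin, then (maternal duplications only)
    meiosis I vs II."""
    params = params or AnalysisParams()
    sites = collect_informative_sites(snp_rows, event_kind, region, params)

    n_mat = sum(s.support == SiteSupport.MATERNAL for s in sites)
    n_pat = sum(s.support == SiteSupport.PATERNAL for s in sites)
    origin_winner = decide(n_mat, n_pat, params)
    origin = {"A": MATERNAL, "B": PATERNAL, "ambiguous": UNKNOWN}[origin_winner]

    timing = Timing.NA
    n_mi = n_mii = 0
    if origin == MATERNAL and event_kind == "duplication":
        n_mi = sum(s.support == SiteSupport.HETEROLOGOUS_MI for s in sites)
        n_mii = sum(s.support == SiteSupport.HOMOLOGOUS_MII for s in sites)
        winner = decide(n_mi, n_mii, params)
        timing = {"A": Timing.MI, "B": Timing.MII, "ambiguous": Timing.AMBIGUOUS}[winner]

    return OriginTimingCall(
        event_id=event_id,
        origin=origin,
        timing=timing,
        n_support_maternal=n_mat,
        n_support_paternal=n_pat,
        n_support_mi=n_mi,
        n_support_mii=n_mii,
    )
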