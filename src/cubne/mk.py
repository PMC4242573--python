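"""Polarized McDonald-Kreitman test on preferred/unpreferred codons.

The test contrasts the fixed:polymorphic ratio of unpreferred-to-preferred
versus preferred-to-unpreferred synonymous changes at third codon
positions in a population sample, with ancestral states polarized against
the consensus of two outgroup genomes. Under selection favoring preferred
codons, unpreferred->preferred changes fix at a higher rate. Two controls
guard the inference:

* an intron null — segregating intronic sites are forced into the third
  position of an "imaginary codon" built from the two preceding bases in
  coding orientation, and run through the identical machinery, so purely
  mutational asymmetries register there too;
* a CpG mis-polarization filter — two independent CpG->TpG deaminations on
  the outgroup lineages mimic an unpreferred->preferred change in the
  ingroup. Sites whose quintet context matches either hypermutable pattern
  (outgroup ..TG. with ingroup-derived ..CG., or outgroup .CA.. with
  ingroup-derived .CG..) are flagged and can be excluded.

All 2x2 statistics use Pearson's chi-square with Yates continuity
correction; chi2/N (reported per 1,000 sites) normalizes the deviation by
table size so exon and intron tables of very different size compare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import reverse_complement

from .seqio import BASES, CodonCounts, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

UNPREF_TO_PREF = "unpref_to_pref"
PREF_TO_UNPREF = "pref_to_unpref"
OTHER = "other"


@dataclass
class PreferenceMap:
    """Genome-wide preferred/unpreferred codon of each synonymous family.

    Sixfold families are split into their fourfold and twofold subfamilies
    before ranking, so every family contributes exactly one preferred (most
    used) and one unpreferred (least used) codon.
    """

    preferred: dict[str, str]
    unpreferred: dict[str, str]
    counts_used: dict[str, dict[str, int]] = field(default_factory=dict)
    split_sixfold: bool = True

    def classes_of(self, codon: str, code: GeneticCode = STANDARD_CODE) -> str | None:
        return code.family_of(codon, self.split_sixfold)


@dataclass
class PolarizedSite:
    """A polarized third-position (or imaginary-codon) site."""

    site_id: str
    region: str  # exon | intron
    quintet_ancestral: str  # outgroup-consensus context, coding orientation
    quintet_derived: str  # same context with the derived base at b3
    ancestral_codon: str
    derived_codon: str
    direction: str = OTHER
    status: str = "polymorphic"  # polymorphic | fixed
    cpg_suspect: bool = False
    boundary_distance: int | None = None


@dataclass
class MKTable:
    """2x2 fixed/polymorphic contrast between the two direction classes."""

    poly_pref_to_unpref: int
    fixed_pref_to_unpref: int
    poly_unpref_to_pref: int
    fixed_unpref_to_pref: int
    chi2: float = np.nan
    p: float = np.nan
    region: str = ""
    cpg_filtered: bool = False

    @property
    def n(self) -> int:
        return (
            self.poly_pref_to_unpref + self.fixed_pref_to_unpref
            + self.poly_unpref_to_pref + self.fixed_unpref_to_pref
        )

    @property
    def chi2_per_1000(self) -> float:
        return 1000.0 * self.chi2 / self.n if self.n else np.nan

    @property
    def prop_fixed_pref_to_unpref(self) -> float:
        tot = self.poly_pref_to_unpref + self.fixed_pref_to_unpref
        return self.fixed_pref_to_unpref / tot if tot else np.nan

    @property
    def prop_fixed_unpref_to_pref(self) -> float:
        tot = self.poly_unpref_to_pref + self.fixed_unpref_to_pref
        return self.fixed_unpref_to_pref / tot if tot else np.nan


def designate_preferences(
    genome_counts: CodonCounts,
    code: GeneticCode = STANDARD_CODE,
    split_sixfold: bool = True,
) -> PreferenceMap:
    """Most/least used codon per family from genome-wide codon counts.

    Ties are broken lexicographically with a warning; zero-count families
    are excluded.
    """
    preferred, unpreferred, used = {}, {}, {}
    for fam, codons in code.families(split_sixfold).items():
        counts = {c: genome_counts.count(c) for c in codons}
        if sum(counts.values()) == 0:
            logger.warning("designate_preferences: family %s has zero counts", fam)
            continue
        if len(set(counts.values())) < len(counts):
            logger.warning(
                "designate_preferences: tie in family %s broken lexicographically", fam
            )
        preferred[fam] = min(counts, key=lambda c: (-counts[c], c))
        unpreferred[fam] = min(
            (c for c in codons if c != preferred[fam]),
            key=lambda c: (counts[c], c),
        )
        used[fam] = counts
    return PreferenceMap(
        preferred=preferred, unpreferred=unpreferred,
        counts_used=used, split_sixfold=split_sixfold,
    )


def polarize_site(
    sample_bases,
    outgroup1: str,
    outgroup2: str,
) -> tuple[str, str, str] | None:
    """Assign (ancestral, derived, status) from a population sample and two
    outgroup bases, or None when the site cannot be polarized.

    The ancestral state is the shared outgroup base; disagreeing outgroups,
    triallelic samples, and unpolarizable configurations are excluded.
    Monomorphic samples matching the outgroup consensus are invariant and
    also return None.
    """
    if outgroup1 != outgroup2 or outgroup1 not in BASES:
        return None
    alleles = sorted(set(sample_bases))
    if not alleles or any(a not in BASES for a in alleles) or len(alleles) > 2:
        return None
    anc = outgroup1
    if len(alleles) == 2:
        if anc not in alleles:
            return None
        derived = alleles[0] if alleles[1] == anc else alleles[1]
        return anc, derived, "polymorphic"
    if alleles[0] != anc:
        return anc, alleles[0], "fixed"
    return None  # invariant


def classify_direction(
    ancestral_codon: str,
    derived_codon: str,
    prefs: PreferenceMap,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Direction class of a codon change under a preference map.

    Only exchanges between a family's single preferred and single
    unpreferred codon count; every other change (middle-ranked synonymous,
    nonsynonymous, cross-family) is "other" and never enters the table.
    """
    fam_a = code.family_of(ancestral_codon, prefs.split_sixfold)
    fam_d = code.family_of(derived_codon, prefs.split_sixfold)
    if fam_a is None or fam_a != fam_d or fam_a not in prefs.preferred:
        return OTHER
    pref, unpref = prefs.preferred[fam_a], prefs.unpreferred[fam_a]
    if ancestral_codon == unpref and derived_codon == pref:
        return UNPREF_TO_PREF
    if ancestral_codon == pref and derived_codon == unpref:
        return PREF_TO_UNPREF
    return OTHER


def cpg_suspect(site: PolarizedSite) -> bool:
    """Flag quintets matching either CpG hypermutation mis-polarization
    pattern (outgroup ..TG. -> ingroup ..CG., or .CA.. -> .CG..)."""
    qa, qd = site.quintet_ancestral.upper(), site.quintet_derived.upper()
    if len(qa) != 5 or len(qd) != 5:
        return False
    pattern1 = qa[2] == "T" and qa[3] == "G" and qd[2] == "C" and qd[3] == "G"
    pattern2 = qa[1] == "C" and qa[2] == "A" and qd[1] == "C" and qd[2] == "G"
    return pattern1 or pattern2


def make_exon_site(
    site_id: str,
    codon_context: str,  # the 2 bases before + site + 2 after, coding orient.
    sample_bases,
    outgroup1: str,
    outgroup2: str,
    prefs: PreferenceMap,
    code: GeneticCode = STANDARD_CODE,
) -> PolarizedSite | None:
    """Build a polarized exonic third-position site from its quintet.

    ``codon_context`` is b1..b5 with b3 the varying third position; b1 b2
    are the first two bases of the codon, b4 b5 the first two of the next.
    """
    pol = polarize_site(sample_bases, outgroup1, outgroup2)
    if pol is None:
        return None
    anc, der, status = pol
    b = codon_context.upper()
    if len(b) != 5:
        return None
    site = PolarizedSite(
        site_id=site_id,
        region="exon",
        quintet_ancestral=b[:2] + anc + b[3:],
        quintet_derived=b[:2] + der + b[3:],
        ancestral_codon=b[0] + b[1] + anc,
        derived_codon=b[0] + b[1] + der,
        status=status,
    )
    site.direction = classify_direction(site.ancestral_codon, site.derived_codon, prefs, code)
    site.cpg_suspect = cpg_suspect(site)
    return site


def build_intron_sites(
    intron_seq: str,
    strand: str,
    site_calls,
    prefs: PreferenceMap,
    boundary_exclusion: int = 20,
    code: GeneticCode = STANDARD_CODE,
    site_prefix: str = "intron",
) -> list[PolarizedSite]:
    """Imaginary-codon sites from an intron.

    ``intron_seq`` is the intron in genome orientation; ``site_calls`` is a
    sequence of ``(offset, sample_bases, outgroup1, outgroup2)`` with
    offsets and bases in genome orientation. Minus-strand genes are
    reverse-complemented into coding orientation first. Each retained site
    becomes the third position of an imaginary codon made of the two
    immediately preceding bases in coding orientation; sites within
    ``boundary_exclusion`` bases of either intron end, or too close to the
    intron start for a codon context, are excluded.
    """
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    seq = intron_seq.upper()
    length = len(seq)
    if strand == "-":
        seq = reverse_complement(seq)
    comp = dict(zip("ACGT", "TGCA"))
    sites = []
    for offset, sample_bases, out1, out2 in site_calls:
        if strand == "-":
            offset = length - 1 - offset
            sample_bases = [comp.get(b, b) for b in sample_bases]
            out1, out2 = comp.get(out1, out1), comp.get(out2, out2)
        if min(offset, length - 1 - offset) < boundary_exclusion:
            continue
        if offset < 2 or offset > length - 3:
            continue  # no room for the codon/quintet context
        pol = polarize_site(sample_bases, out1, out2)
        if pol is None:
            continue
        anc, der, status = pol
        ctx = seq[offset - 2: offset + 3]
        site = PolarizedSite(
            site_id=f"{site_prefix}:{offset}",
            region="intron",
            quintet_ancestral=ctx[:2] + anc + ctx[3:],
            quintet_derived=ctx[:2] + der + ctx[3:],
            ancestral_codon=ctx[0] + ctx[1] + anc,
            derived_codon=ctx[0] + ctx[1] + der,
            status=status,
            boundary_distance=min(offset, length - 1 - offset),
        )
        site.direction = classify_direction(
            site.ancestral_codon, site.derived_codon, prefs, code
        )
        site.cpg_suspect = cpg_suspect(site)
        sites.append(site)
    return sites


def chi2_2x2(a: int, b: int, c: int, d: int, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square (df=1) of the table [[a, b], [c, d]].

    Yates continuity correction is applied by default; a zero marginal
    leaves the statistic undefined (NaN, NaN).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res[0]), float(res[1])


def mk_table(
    sites,
    cpg_filter: bool = False,
    continuity: bool = True,
    region: str = "",
) -> MKTable:
    """Assemble the 2x2 fixed/polymorphic table and its statistics.

    Sites with direction "other" never enter; with ``cpg_filter`` on,
    CpG-suspect sites are dropped before counting.
    """
    cells = {(PREF_TO_UNPREF, "polymorphic"): 0, (PREF_TO_UNPREF, "fixed"): 0,
             (UNPREF_TO_PREF, "polymorphic"): 0, (UNPREF_TO_PREF, "fixed"): 0}
    for s in sites:
        if s.direction == OTHER:
            continue
        if cpg_filter and s.cpg_suspect:
            continue
        cells[(s.direction, s.status)] += 1
    table = MKTable(
        poly_pref_to_unpref=cells[(PREF_TO_UNPREF, "polymorphic")],
        fixed_pref_to_unpref=cells[(PREF_TO_UNPREF, "fixed")],
        poly_unpref_to_pref=cells[(UNPREF_TO_PREF, "polymorphic")],
        fixed_unpref_to_pref=cells[(UNPREF_TO_PREF, "fixed")],
        region=region,
        cpg_filtered=cpg_filter,
    )
    table.chi2, table.p = chi2_2x2(
        table.poly_pref_to_unpref, table.fixed_pref_to_unpref,
        table.poly_unpref_to_pref, table.fixed_unpref_to_pref,
        continuity=continuity,
    )
    if not np.isfinite(table.chi2):
        logger.warning("mk_table(%s): zero marginal, chi-square undefined", region)
    return table


def mk_table_from_counts(
    poly_pref_to_unpref: int,
    fixed_pref_to_unpref: int,
    poly_unpref_to_pref: int,
    fixed_unpref_to_pref: int,
    continuity: bool = True,
    region: str = "",
) -> MKTable:
    """MK statistics from pre-counted cells (e.g. a published table)."""
    table = MKTable(
        poly_pref_to_unpref=poly_pref_to_unpref,
        fixed_pref_to_unpref=fixed_pref_to_unpref,
        poly_unpref_to_pref=poly_unpref_to_pref,
        fixed_unpref_to_pref=fixed_unpref_to_pref,
        region=region,
    )
    table.chi2, table.p = chi2_2x2(
        poly_pref_to_unpref, fixed_pref_to_unpref,
        poly_unpref_to_pref, fixed_unpref_to_pref,
        continuity=continuity,
    )
    return table


def mk_report(tables: list[MKTable]) -> pd.DataFrame:
    """Flatten MK tables into the region x direction x status report."""
    rows = []
    for t in tables:
        for direction, poly, fixed, prop in [
            (PREF_TO_UNPREF, t.poly_pref_to_unpref, t.fixed_pref_to_unpref,
             t.prop_fixed_pref_to_unpref),
            (UNPREF_TO_PREF, t.poly_unpref_to_pref, t.fixed_unpref_to_pref,
             t.prop_fixed_unpref_to_pref),
        ]:
            rows.append({
                "region": t.region,
                "cpg_filtered": t.cpg_filtered,
                "direction": direction,
                "polymorphic": poly,
                "fixed": fixed,
                "prop_fixed": prop,
                "chi2": t.chi2,
                "p": t.p,
                "chi2_per_1000": t.chi2_per_1000,
            })
    return pd.DataFrame(rows)


def sites_from_table(table: pd.DataFrame, prefs: PreferenceMap) -> list[PolarizedSite]:
    """Polarized sites from a tabular site file.

    Expected columns: site_id, region (exon|intron), context (5-base
    quintet in coding orientation, reference base at the centre), sample
    (string of sampled ingroup bases), out1, out2, and boundary_dist
    (introns; -1/NaN for exons). Intronic sites closer than 20 bp to a
    boundary are assumed to be pre-filtered or carry their distance here.
    """
    sites = []
    for row in table.itertuples(index=False):
        pol = polarize_site(str(row.sample), str(row.out1), str(row.out2))
        if pol is None:
            continue
        anc, der, status = pol
        ctx = str(row.context).upper()
        if len(ctx) != 5:
            continue
        bd = getattr(row, "boundary_dist", None)
        bd = None if bd is None or (isinstance(bd, float) and np.isnan(bd)) or bd < 0 else int(bd)
        site = PolarizedSite(
            site_id=str(row.site_id),
            region=str(row.region),
            quintet_ancestral=ctx[:2] + anc + ctx[3:],
            quintet_derived=ctx[:2] + der + ctx[3:],
            ancestral_codon=ctx[0] + ctx[1] + anc,
            derived_codon=ctx[0] + ctx[1] + der,
            status=status,
            boundary_distance=bd,
        )
        site.direction = classify_direction(site.ancestral_codon, site.derived_codon, prefs)
        site.cpg_suspect = cpg_suspect(site)
        sites.append(site)
    return sites
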