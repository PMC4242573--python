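"""Codon usage bias metrics: ENC and the background-corrected ENCp.

The effective number of codons (ENC) measures how far a gene's synonymous
codon usage departs from the uniform-usage null; it ranges from 20 (every
amino acid encoded by a single codon, maximal bias) to 61 (all synonymous
codons used equally, no bias). ENC's null assumes the four nucleotides are
equally frequent, so mutational bias alone registers as codon bias. ENCp
replaces the uniform null with expected codon frequencies derived from the
local background base composition (flanking sequence or introns), so only
departures beyond the mutational background count as bias.

Per synonymous family ``a`` with ``k_a`` codons, ``n_a`` observed codons
and within-family frequencies ``p_i``:

    F_a  = (n_a * sum_i p_i**2 - 1) / (n_a - 1)                  (ENC)
    X2_a = n_a * sum_i (p_i - e_i)**2 / e_i
    F'_a = (X2_a + n_a - k_a) / (k_a * (n_a - 1))                (ENCp)

with ``e_i`` the background-expected within-family frequencies. Class
means over degeneracy classes (9 twofold, 1 threefold, 5 fourfold, 3
sixfold families in the standard code) combine as

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

and identically for ENCp with F' in place of F. With a uniform background
F' reduces to F exactly, so ENCp equals ENC. The summed family chi-square
also yields a per-gene significance test of observed vs expected usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seqio import BASES, CodonCounts, GeneticCode, STANDARD_CODE, TranscriptRecord

logger = logging.getLogger(__name__)

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class BackgroundComposition:
    """A/C/G/T frequencies of a gene's neutral background sequence."""

    freqs: np.ndarray  # length 4, order ACGT, sums to 1
    source: str = "flank"  # flank | introns | uniform
    total_bases: int = 0

    @classmethod
    def uniform(cls) -> "BackgroundComposition":
        return cls(np.full(4, 0.25), source="uniform")

    @classmethod
    def from_sequence(cls, seq: str, source: str = "flank") -> "BackgroundComposition":
        seq = seq.upper()
        counts = np.array([seq.count(b) for b in BASES], dtype=float)
        total = int(counts.sum())  # ambiguous bases excluded entirely
        if total == 0:
            raise ValueError("background sequence contains no unambiguous bases")
        return cls(counts / total, source=source, total_bases=total)

    def freq(self, base: str) -> float:
        return float(self.freqs[BASES.index(base)])


@dataclass
class ENCResult:
    """Per-gene ENC/ENCp values with the chi-square significance test."""

    gene_id: str
    enc: float
    encp: float
    enc_raw: float  # uncapped
    encp_raw: float
    chi2: float
    df: int
    p: float
    n_codons: int = 0
    fhat: dict[str, float] = field(default_factory=dict)
    fhat_prime: dict[str, float] = field(default_factory=dict)
    background_source: str = "uniform"


class DroppedGene(Exception):
    """Gene cannot enter an analysis (e.g. too little intronic sequence)."""


def background_composition(
    record: TranscriptRecord,
    source: str = "flank",
    min_intron_bases: int = 1000,
) -> BackgroundComposition:
    """Estimate background base composition from flanks or introns.

    ``flank`` pools both flanking sequences (up to 2 kb each, 4 kb total);
    ``introns`` pools the concatenated introns and requires at least
    ``min_intron_bases`` of intronic sequence, otherwise the gene is
    dropped from the intron-background analysis (:class:`DroppedGene`).
    """
    if source == "flank":
        seq = record.flank5 + record.flank3
        if not seq:
            raise DroppedGene(f"{record.gene_id}: no flanking sequence available")
    elif source == "introns":
        seq = "".join(record.introns)
        n_clean = sum(seq.upper().count(b) for b in BASES)
        if n_clean < min_intron_bases:
            raise DroppedGene(
                f"{record.gene_id}: {n_clean} intronic bases < required "
                f"{min_intron_bases}; dropped from intron-background analysis"
            )
    else:
        raise ValueError(f"unknown background source {source!r}")
    return BackgroundComposition.from_sequence(seq, source=source)


def expected_family_frequencies(
    code: GeneticCode = STANDARD_CODE,
    background: BackgroundComposition | None = None,
    split_sixfold: bool = False,
) -> dict[str, np.ndarray]:
    """Background-expected within-family codon frequencies ``e_i``.

    Each codon's weight is the product of the background frequency of its
    three bases; weights are normalized within each family. Families whose
    expected frequencies all vanish (a zero background frequency) are
    excluded with a warning.
    """
    if background is None:
        background = BackgroundComposition.uniform()
    out: dict[str, np.ndarray] = {}
    for fam, codons in code.families(split_sixfold).items():
        w = np.array(
            [np.prod([background.freq(b) for b in codon]) for codon in codons]
        )
        total = w.sum()
        if total <= 0:
            logger.warning(
                "family %s excluded: zero expected frequency under background", fam
            )
            continue
        out[fam] = w / total
    return out


def _family_stats(
    counts: CodonCounts,
    code: GeneticCode,
    expected: dict[str, np.ndarray] | None,
    split_sixfold: bool = False,
) -> pd.DataFrame:
    """Per-family n_a, k_a, F, and (if expected given) chi2 and F'."""
    rows = []
    for fam, codons in code.families(split_sixfold).items():
        n_fam = counts.family_counts(fam, code, split_sixfold).astype(float)
        n_a, k_a = n_fam.sum(), len(codons)
        row = {"family": fam, "k": k_a, "n": n_a, "F": np.nan, "chi2": np.nan,
               "Fp": np.nan, "df": k_a - 1}
        if n_a >= 2:
            p = n_fam / n_a
            row["F"] = (n_a * (p ** 2).sum() - 1.0) / (n_a - 1.0)
            if expected is not None and fam in expected:
                e = expected[fam]
                chi2 = n_a * ((p - e) ** 2 / e).sum()
                row["chi2"] = chi2
                row["Fp"] = (chi2 + n_a - k_a) / (k_a * (n_a - 1.0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")


# Degeneracy classes of the standard code (no sixfold split): the ENC
# combination weights each class mean by its family count.
_CLASS_WEIGHT = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


def _combine_class_means(fam: pd.DataFrame, column: str) -> float:
    """2 + sum_c (n_families_c / Fbar_c), with the standard F3 imputation."""
    means: dict[int, float] = {}
    for k, grp in fam.groupby("k"):
        vals = grp[column].dropna()
        if len(vals):
            means[k] = float(vals.mean())
    if 3 not in means and 2 in means and 4 in means:
        means[3] = 0.5 * (means[2] + means[4])  # standard ENC convention
    missing = [k for k in _CLASS_WEIGHT if k not in means]
    if missing:
        return np.nan  # no imputation path: value undefined for this gene
    if any(means[k] <= 0 for k in _CLASS_WEIGHT):
        # a zero homozygosity class (maximal within-family diversity) pushes
        # the raw value past the cap; report +inf, capped to 61 by callers
        return np.inf
    return 2.0 + sum(_CLASS_WEIGHT[k] / means[k] for k in _CLASS_WEIGHT)


def enc(counts: CodonCounts, code: GeneticCode = STANDARD_CODE) -> float:
    """Effective number of codons, capped to [20, 61]; NaN if undefined."""
    fam = _family_stats(counts, code, expected=None)
    raw = _combine_class_means(fam, "F")
    return np.nan if np.isnan(raw) else float(np.clip(raw, ENC_MIN, ENC_MAX))


def encp(
    counts: CodonCounts,
    background: BackgroundComposition | None = None,
    code: GeneticCode = STANDARD_CODE,
    gene_id: str | None = None,
    min_expected: float = 1.0,
) -> ENCResult:
    """ENC and background-corrected ENCp with chi-square significance.

    Families enter the chi-square sum only when every expected count
    ``e_i * n_a`` reaches ``min_expected`` (Pearson validity guard); the
    class means for ENCp itself use every family with ``n_a >= 2``.
    """
    expected = expected_family_frequencies(code, background)
    fam = _family_stats(counts, code, expected)
    enc_raw = _combine_class_means(fam, "F")
    encp_raw = _combine_class_means(fam, "Fp")

    ok = fam["chi2"].notna()
    for name, row in fam[ok].iterrows():
        e = expected[name]
        if (e * row["n"]).min() < min_expected:
            ok[name] = False
    chi2 = float(fam.loc[ok, "chi2"].sum()) if ok.any() else np.nan
    df = int(fam.loc[ok, "df"].sum()) if ok.any() else 0
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    if not ok.any():
        logger.warning("encp: no usable family for gene %s", gene_id or counts.gene_id)

    def cap(x: float) -> float:
        return np.nan if np.isnan(x) else float(np.clip(x, ENC_MIN, ENC_MAX))

    return ENCResult(
        gene_id=gene_id or counts.gene_id,
        enc=cap(enc_raw),
        encp=cap(encp_raw),
        enc_raw=float(enc_raw),
        encp_raw=float(encp_raw),
        chi2=chi2,
        df=df,
        p=p,
        n_codons=counts.n,
        fhat=fam["F"].dropna().to_dict(),
        fhat_prime=fam["Fp"].dropna().to_dict(),
        background_source=background.source if background else "uniform",
    )


def encp_significance(
    counts: CodonCounts,
    background: BackgroundComposition | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[float, int, float]:
    """Pearson chi-square of observed vs background-expected codon usage."""
    res = encp(counts, background, code)
    return res.chi2, res.df, res.p


def bh_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    if valid.any():
        flags[valid] = multipletests(p[valid], alpha=alpha, method="fdr_bh")[0]
    return flags


def bh_qvalues(p_values) -> np.ndarray:
    """BH-adjusted p-values (NaN propagated)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def aggregate_transcript_choices(table: pd.DataFrame, value: str = "encp") -> pd.Series:
    """Average a per-gene statistic over repeated random transcript choices.

    ``table`` has columns ``gene_id``, ``iteration`` and the value column.
    Genes missing from some iterations are averaged over the iterations in
    which they appear (logged).
    """
    grouped = table.groupby("gene_id")[value]
    sizes = grouped.size()
    n_iter = table["iteration"].nunique()
    short = sizes[sizes < n_iter]
    for gene, k in short.items():
        logger.info(
            "gene %s present in %d/%d iterations; averaged over available", gene, k, n_iter
        )
    return grouped.mean()


def per_family_encp(
    counts: CodonCounts,
    background: BackgroundComposition | None,
    family: str,
    code: GeneticCode = STANDARD_CODE,
    split_sixfold: bool = True,
) -> float:
    """Family-restricted effective codon number, 1/F'_a capped to [1, k_a].

    NaN when the family has fewer than two observed codons.
    """
    expected = expected_family_frequencies(code, background, split_sixfold)
    fam = _family_stats(counts, code, expected, split_sixfold)
    if family not in fam.index:
        raise KeyError(f"unknown family {family!r}")
    row = fam.loc[family]
    if not np.isfinite(row["Fp"]) or row["Fp"] <= 0:
        return np.nan
    return float(np.clip(1.0 / row["Fp"], 1.0, row["k"]))


def enc_table(
    records_counts: list[tuple[str, CodonCounts, BackgroundComposition | None]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene ENC/ENCp report with BH-corrected q-values."""
    rows = []
    for gene_id, counts, bg in records_counts:
        r = encp(counts, bg, gene_id=gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "n_codons": r.n_codons,
                "enc": r.enc,
                "encp": r.encp,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "background_source": r.background_source,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = bh_qvalues(df["p"])
        df["significant"] = bh_correct(df["p"], alpha=alpha)
    return df
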