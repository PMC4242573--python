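"""Synthetic genomes, polymorphism, alignments, and trait trees.

Every input the pipeline consumes can be generated here with the
statistical structure the analyses assume:

* coding sequence is drawn i.i.d. per codon from the mutation-selection
  stationary distribution pi_j ∝ pistar_j1 * pistar_j2 * pistar_j3 *
  exp(F_j) — the same stationary law as the substitution model in
  :mod:`cubne.models`, so generator and fitter share one definition;
* introns and flanks are drawn from the mutational base frequencies alone
  (no selection, no reading frame), giving ENCp its background;
* divergence/polymorphism at third codon positions follows a three-branch
  history (ingroup lineage plus two outgroup lineages from a common
  ancestor): fixed differences on the ingroup lineage arise at rate
  mu_ij * h(S_ij) (selection-weighted fixation), polymorphic sites at a
  neutral rate with derived-allele sample counts from the 1/k neutral
  frequency spectrum, and outgroup lineages evolve neutrally except that
  CpG-context deaminations (C->T at CpG on either strand) are accelerated
  by a configurable multiplier — two independent outgroup deaminations
  produce exactly the mis-polarization artifact the CpG filter targets;
* pairwise codon alignments are simulated from the substitution model's
  transition probabilities over a branch length t;
* tip traits evolve by Brownian motion on a (possibly polytomous) tree
  with Pagel-lambda covariance and a linear link between predictor and
  response.

All randomness flows from a single seed; identical configurations produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import models
from .mk import PreferenceMap
from .seqio import BASES, GeneticCode, STANDARD_CODE, TranscriptRecord

logger = logging.getLogger(__name__)

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults emulate a mammalian study system: ~500-codon genes, 40% GC
    mutational background, transition/transversion ratio 2, roughly 1%
    ingroup-lineage divergence to the outgroup split and 0.5% of third
    positions segregating in a 176-chromosome population sample.
    """

    seed: int = 0
    # genes
    n_genes: int = 100
    codons_per_gene: int = 500
    n_exons: int = 3
    intron_length: int = 1500
    flank_length: int = 2000
    p_x_linked: float = 0.05
    p_minus_strand: float = 0.5
    # mutation-selection model
    selection_s: float = 0.0  # scaled coefficient favoring one codon/family
    pi_star: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # ACGT
    kappa: float = 2.0
    # polymorphism / divergence
    sample_size: int = 176  # ingroup chromosomes
    substitution_rate: float = 0.01  # ingroup-lineage fixation scale
    polymorphism_rate: float = 0.005  # probability a site segregates
    outgroup_rate: float = 0.012  # per outgroup lineage
    cpg_multiplier: float = 1.0  # CpG transition acceleration (outgroups)
    cpg_all_branches: bool = False
    # trait tree
    n_tips: int = 41
    tree_newick: str | None = None
    brownian_sigma2: float = 1.0
    lambda_x: float = 1.0
    lambda_y: float = 1.0
    trait_slope: float = 0.0
    trait_intercept: float = 0.0
    noise_sigma2: float = 1.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# Fitness vectors and stationary codon sampling
# ---------------------------------------------------------------------------

def build_fitness(
    selection_s: float | dict[str, float] = 0.0,
    code: GeneticCode = STANDARD_CODE,
    split_sixfold: bool = True,
    favored: dict[str, str] | None = None,
) -> np.ndarray:
    """Codon fitness vector giving one favored codon per family F = S.

    ``selection_s`` is a scalar applied to every family or a per-family
    map; the favored codon defaults to the lexicographically first codon
    of each family (deterministic and independent of mutation bias).
    """
    F = np.zeros(len(code.codons))
    fams = code.families(split_sixfold)
    for fam, codons in fams.items():
        s = selection_s.get(fam, 0.0) if isinstance(selection_s, dict) else selection_s
        target = favored.get(fam) if favored else sorted(codons)[0]
        F[code.codon_index[target]] = s
    return F


def stationary_codon_distribution(config: SimulationConfig) -> np.ndarray:
    F = build_fitness(config.selection_s)
    return models.stationary_distribution(np.asarray(config.pi_star), F)


def _random_bases(rng: np.random.Generator, pi_star, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=pi_star)])


def gen_gene(
    config: SimulationConfig,
    rng: np.random.Generator,
    index: int = 0,
) -> TranscriptRecord:
    """One synthetic transcript: stationary-law CDS, neutral introns/flanks."""
    pi = stationary_codon_distribution(config)
    pis = np.asarray(config.pi_star, dtype=float)
    codon_idx = rng.choice(len(pi), size=config.codons_per_gene, p=pi)
    cds = "".join(STANDARD_CODE.codons[i] for i in codon_idx)
    introns = [
        _random_bases(rng, pis, config.intron_length)
        for _ in range(max(0, config.n_exons - 1))
    ]
    gid = f"gene{index:04d}"
    return TranscriptRecord(
        gene_id=gid,
        transcript_id=f"{gid}.t1",
        chrom="chrX" if rng.random() < config.p_x_linked else "chr1",
        strand="-" if rng.random() < config.p_minus_strand else "+",
        cds=cds,
        introns=introns,
        flank5=_random_bases(rng, pis, config.flank_length),
        flank3=_random_bases(rng, pis, config.flank_length),
    )


def gen_genes(config: SimulationConfig) -> list[TranscriptRecord]:
    rng = config.rng(stream=1)
    return [gen_gene(config, rng, i) for i in range(config.n_genes)]


def true_preferences(
    config: SimulationConfig,
    code: GeneticCode = STANDARD_CODE,
    split_sixfold: bool = True,
) -> PreferenceMap:
    """Preference map implied by the generating stationary distribution."""
    pi = stationary_codon_distribution(config)
    preferred, unpreferred = {}, {}
    for fam, codons in code.families(split_sixfold).items():
        masses = {c: pi[code.codon_index[c]] for c in codons}
        preferred[fam] = min(masses, key=lambda c: (-masses[c], c))
        unpreferred[fam] = min(
            (c for c in codons if c != preferred[fam]),
            key=lambda c: (masses[c], c),
        )
    return PreferenceMap(preferred=preferred, unpreferred=unpreferred,
                         split_sixfold=split_sixfold)


# ---------------------------------------------------------------------------
# Polymorphism and divergence at third positions
# ---------------------------------------------------------------------------

def _mutation_weight(a: str, b: str, kappa: float, pi_star) -> float:
    return (kappa if _TS_PARTNER[a] == b else 1.0) * pi_star[BASES.index(b)]


def _third_position_moves(config: SimulationConfig):
    """Per ancestral codon: derived codons reachable by a third-position
    change with their mutation weights and fixation factors."""
    F = build_fitness(config.selection_s)
    pis = np.asarray(config.pi_star)
    moves: dict[str, list[tuple[str, str, float, float]]] = {}
    for codon in STANDARD_CODE.codons:
        opts = []
        for b in BASES:
            if b == codon[2]:
                continue
            derived = codon[:2] + b
            mu = _mutation_weight(codon[2], b, config.kappa, pis)
            j = STANDARD_CODE.codon_index.get(derived)
            if j is None:
                continue  # change creates a stop codon: lethal, never seen
            s = F[j] - F[STANDARD_CODE.codon_index[codon]]
            opts.append((derived, b, mu, float(models.fixation_factor(np.array([s]))[0])))
        moves[codon] = opts
    return moves


def _neutral_moves(kappa: float, pi_star):
    """Base -> [(derived base, mutation weight)] for intron sites."""
    return {
        a: [(b, _mutation_weight(a, b, kappa, pi_star)) for b in BASES if b != a]
        for a in BASES
    }


def _sfs_counts(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Derived-allele sample counts from the neutral 1/k spectrum."""
    k = np.arange(1, n)
    p = (1.0 / k) / (1.0 / k).sum()
    return rng.choice(k, size=size, p=p)


def _evolve_outgroup(
    anc: str,
    left: str,
    right: str,
    config: SimulationConfig,
    u: float,
    rng: np.random.Generator,
    neutral: dict,
) -> str:
    """One outgroup lineage at one site; ``left``/``right`` are the
    neighboring bases (coding orientation) fixing the CpG context."""
    rate = config.outgroup_rate
    cpg_rate = rate * config.cpg_multiplier
    if anc == "C" and right == "G" and u < cpg_rate:
        return "T"  # CpG -> TpG deamination
    if anc == "G" and left == "C" and u < cpg_rate:
        return "A"  # deamination on the opposite strand
    if u < rate:
        opts = neutral[anc]
        w = np.array([m for _, m in opts])
        return opts[int(rng.choice(len(opts), p=w / w.sum()))][0]
    return anc


def gen_polymorphism_divergence(config: SimulationConfig) -> pd.DataFrame:
    """Site table of ingroup polymorphism + two outgroup states.

    Returns one row per site at which anything happened (an ingroup
    fixation or polymorphism, or an outgroup substitution), with columns
    ``site_id, region, context`` (ancestral 5-base quintet in coding
    orientation), ``sample`` (ingroup sampled bases as a string), ``out1,
    out2, boundary_dist`` (introns only, -1 for exons). Exonic third
    positions feel selection through the fixation factor h(S); intronic
    sites are neutral. Invariant sites never appear — they cannot enter an
    MK table.
    """
    rng = config.rng(stream=2)
    moves = _third_position_moves(config)
    neutral = _neutral_moves(config.kappa, np.asarray(config.pi_star))
    pi = stationary_codon_distribution(config)
    pis = np.asarray(config.pi_star)
    n = config.sample_size
    rows = []

    def _site_scheme(opts):
        """Precompute the event edges for one ancestral state.

        opts: [(derived_base, mu, h)]. Events are ordered: fixations of
        each derived base (rate ∝ mu*h), then polymorphisms (rate ∝ mu).
        """
        bases = [b for b, _, _ in opts]
        mu = np.array([m for _, m, _ in opts])
        h = np.array([hh for _, _, hh in opts])
        mu_total = mu.sum()
        p_fix = config.substitution_rate * (mu * h) / mu_total
        p_poly = config.polymorphism_rate * mu / mu_total
        edges = np.cumsum(np.concatenate([p_fix, p_poly]))
        return bases, edges

    exon_scheme = {
        c: _site_scheme([(b, m, h) for _, b, m, h in ops])
        for c, ops in moves.items() if ops
    }
    intron_scheme = {
        a: _site_scheme([(b, m, 1.0) for b, m in neutral[a]]) for a in BASES
    }

    def handle_site(region, site_id, anc_base, left2, right2, boundary, scheme):
        bases, edges = scheme
        u_h, u_o1, u_o2 = rng.random(3)
        sample = anc_base * n
        status_hit = u_h < edges[-1]
        if config.cpg_all_branches and config.cpg_multiplier > 1 and not status_hit:
            # optional: CpG hypermutation on the ingroup lineage as well
            extra = config.substitution_rate * (config.cpg_multiplier - 1.0)
            if anc_base == "C" and right2[0] == "G" and rng.random() < extra:
                sample, status_hit = "T" * n, True
            elif anc_base == "G" and left2[-1] == "C" and rng.random() < extra:
                sample, status_hit = "A" * n, True
        if status_hit and sample == anc_base * n:
            kidx = int(np.searchsorted(edges, u_h, side="right"))
            if kidx < len(bases):  # fixation
                sample = bases[kidx] * n
            else:  # polymorphism
                der = bases[kidx - len(bases)]
                k = int(_sfs_counts(rng, n, 1)[0])
                sample = der * k + anc_base * (n - k)
        out1 = _evolve_outgroup(anc_base, left2[-1], right2[0], config, u_o1, rng, neutral)
        out2 = _evolve_outgroup(anc_base, left2[-1], right2[0], config, u_o2, rng, neutral)
        if not status_hit and out1 == anc_base and out2 == anc_base:
            return  # invariant site
        rows.append({
            "site_id": site_id,
            "region": region,
            "context": left2 + anc_base + right2,
            "sample": sample,
            "out1": out1,
            "out2": out2,
            "boundary_dist": boundary,
        })

    for g in range(config.n_genes):
        # exonic third positions
        codon_idx = rng.choice(len(pi), size=config.codons_per_gene, p=pi)
        codons = [STANDARD_CODE.codons[i] for i in codon_idx]
        tail = _random_bases(rng, pis, 2)
        for k, codon in enumerate(codons):
            nxt = codons[k + 1][:2] if k + 1 < len(codons) else tail
            scheme = exon_scheme.get(codon)
            if scheme is None:
                continue
            handle_site("exon", f"g{g}c{k}", codon[2], codon[:2], nxt, -1, scheme)
        # intronic imaginary-codon sites (neutral)
        for i_intron in range(max(0, config.n_exons - 1)):
            seq = _random_bases(rng, pis, config.intron_length)
            for pos in range(2, config.intron_length - 2):
                anc = seq[pos]
                handle_site(
                    "intron", f"g{g}i{i_intron}p{pos}", anc,
                    seq[pos - 2: pos], seq[pos + 1: pos + 3],
                    min(pos, config.intron_length - 1 - pos),
                    intron_scheme[anc],
                )
    return pd.DataFrame(
        rows,
        columns=["site_id", "region", "context", "sample", "out1", "out2", "boundary_dist"],
    )


# ---------------------------------------------------------------------------
# Pairwise codon alignments
# ---------------------------------------------------------------------------

def gen_pairwise_alignment(
    config: SimulationConfig,
    F: np.ndarray | None = None,
    t: float = 0.2,
    n_codons: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Two in-frame codon sequences separated by branch length ``t``.

    The ancestor is sampled from the stationary distribution and the
    descendant from the transition probabilities exp(Q t); by
    reversibility the pair is exchangeable.
    """
    rng = rng if rng is not None else config.rng(stream=3)
    if F is None:
        F = build_fitness(config.selection_s)
    pis = np.asarray(config.pi_star)
    pi = models.stationary_distribution(pis, F)
    Q = models.build_rate_matrix(config.kappa, pis, F)
    P = models.transition_probabilities(Q, pi, t)
    P = P / P.sum(axis=1, keepdims=True)
    n = n_codons or config.codons_per_gene
    anc_idx = rng.choice(len(pi), size=n, p=pi)
    der_idx = np.empty(n, dtype=np.int64)
    for i in np.unique(anc_idx):  # draw descendants grouped by ancestor state
        where = anc_idx == i
        der_idx[where] = rng.choice(len(pi), size=int(where.sum()), p=P[i])
    seq_a = "".join(STANDARD_CODE.codons[i] for i in anc_idx)
    seq_b = "".join(STANDARD_CODE.codons[i] for i in der_idx)
    return seq_a, seq_b


# ---------------------------------------------------------------------------
# Trait trees
# ---------------------------------------------------------------------------

def gen_tree(config: SimulationConfig) -> dendropy.Tree:
    """The configured newick tree, or a seeded pure-birth tree."""
    if config.tree_newick:
        return dendropy.Tree.get(data=config.tree_newick, schema="newick")
    from dendropy.simulate import treesim

    py_rng = random.Random(config.seed + 104729)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=config.n_tips,
        rng=py_rng,
    )
    # The sampler stops at the n-th speciation, leaving a zero-length cherry;
    # extend every tip by the waiting time to the next (uncounted) event so
    # the tree stays ultrametric and its covariance well-conditioned.
    extra = py_rng.expovariate(1.0 * config.n_tips)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"sp{i:02d}"
    return tree


def gen_trait_tree(config: SimulationConfig):
    """Brownian traits on a tree with Pagel-lambda covariance.

    ``x`` is Brownian with variance ``brownian_sigma2`` and lambda
    ``lambda_x``; ``y = intercept + slope * x + e`` where the residual e
    is Brownian with variance ``noise_sigma2`` and lambda ``lambda_y``.
    Returns a :class:`cubne.phylo.TraitTree`.
    """
    from .phylo import TraitTree, phylo_covariance

    tree = gen_tree(config)
    rng = config.rng(stream=4)
    labels, Cx = phylo_covariance(tree, config.lambda_x)
    _, Cy = phylo_covariance(tree, config.lambda_y)
    jitter = 1e-10 * np.eye(len(labels))
    Lx = np.linalg.cholesky(config.brownian_sigma2 * Cx + jitter)
    Ly = np.linalg.cholesky(config.noise_sigma2 * Cy + jitter)
    x = Lx @ rng.standard_normal(len(labels))
    y = config.trait_intercept + config.trait_slope * x + Ly @ rng.standard_normal(len(labels))
    traits = pd.DataFrame({"x": x, "y": y}, index=labels)
    return TraitTree(tree=tree, traits=traits)


# ---------------------------------------------------------------------------
# Dataset assembly on disk
# ---------------------------------------------------------------------------

def assemble_genome(
    records: list[TranscriptRecord],
    spacer: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Lay transcripts onto chromosome sequences and emit BED12 rows.

    Each gene block is flank5 + exon/intron structure + flank3 in coding
    orientation, reverse-complemented onto the chromosome for minus-strand
    genes. Exon boundaries are chosen by splitting the CDS into
    equal-length pieces (n_introns + 1 exons).
    """
    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    bed_rows = []
    for rec in records:
        n_exons = len(rec.introns) + 1
        bounds = np.linspace(0, len(rec.cds), n_exons + 1).astype(int)
        exon_seqs = [rec.cds[bounds[i]: bounds[i + 1]] for i in range(n_exons)]
        body = exon_seqs[0]
        for intron, exon in zip(rec.introns, exon_seqs[1:]):
            body += intron + exon
        block = rec.flank5 + body + rec.flank3
        if rec.strand == "-":
            block = reverse_complement(block)
        pos = chrom_pos.get(rec.chrom, 0)
        chrom_parts.setdefault(rec.chrom, []).append("N" * spacer + block)
        start = pos + spacer + len(rec.flank5)
        end = start + len(body)
        chrom_pos[rec.chrom] = pos + spacer + len(block)
        # exon blocks in genome coordinates
        sizes = [len(s) for s in exon_seqs]
        intron_sizes = [len(i) for i in rec.introns]
        if rec.strand == "-":
            sizes = sizes[::-1]
            intron_sizes = intron_sizes[::-1]
        starts, cursor = [], 0
        for k, sz in enumerate(sizes):
            starts.append(cursor)
            cursor += sz + (intron_sizes[k] if k < len(intron_sizes) else 0)
        rec.exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
        bed_rows.append({
            "chrom": rec.chrom, "start": start, "end": end,
            "name": f"{rec.gene_id}|{rec.transcript_id}", "score": 0,
            "strand": rec.strand, "thick_start": start, "thick_end": end,
            "rgb": "0", "block_count": len(sizes),
            "block_sizes": ",".join(map(str, sizes)),
            "block_starts": ",".join(map(str, starts)),
        })
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    return genome, pd.DataFrame(bed_rows)


def write_vcf(table: pd.DataFrame, path, sample_size: int) -> None:
    """Write the polymorphism/divergence site table as a minimal VCF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=REGION,Number=1,Type=String,Description="exon or intron">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="ancestral quintet context">',
        '##INFO=<ID=OUT1,Number=1,Type=String,Description="outgroup 1 base">',
        '##INFO=<ID=OUT2,Number=1,Type=String,Description="outgroup 2 base">',
        '##INFO=<ID=BD,Number=1,Type=Integer,Description="intron boundary distance">',
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="alt allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="total alleles">',
        "##contig=<ID=sites>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for pos, row in enumerate(table.itertuples(index=False), start=1):
        sample = str(row.sample)
        alleles = sorted(set(sample), key=lambda a: (-sample.count(a), a))
        ref = alleles[0]
        alt = alleles[1] if len(alleles) > 1 else "."
        ac = sample.count(alt) if alt != "." else 0
        info = (
            f"REGION={row.region};CTX={row.context};OUT1={row.out1};"
            f"OUT2={row.out2};BD={row.boundary_dist};AC={ac};AN={len(sample)}"
        )
        lines.append(f"sites\t{pos}\t{row.site_id}\t{ref}\t{alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(config: SimulationConfig, outdir, n_alignments: int = 10) -> dict:
    """Generate and write the full synthetic dataset.

    Emits genome.fa, genes.bed (BED12), centromeres.tsv, sites.tsv and
    sites.vcf, pairwise alignment FASTAs, tree.nwk, traits.tsv, and a
    manifest recording the configuration. Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = gen_genes(config)
    genome, bed = assemble_genome(records)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    bed.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
    cen = pd.DataFrame(
        [
            {"chrom": c, "cen_start": len(s) // 2 - len(s) // 20,
             "cen_end": len(s) // 2 + len(s) // 20, "chrom_length": len(s)}
            for c, s in genome.items()
        ]
    )
    cen.to_csv(out / "centromeres.tsv", sep="\t", index=False)

    # genome-wide codon usage, the basis for preferred/unpreferred codons
    from .seqio import count_codons

    total = None
    for rec in records:
        cc = count_codons(rec.cds)
        total = cc if total is None else total + cc
    pd.DataFrame(
        {"codon": list(STANDARD_CODE.codons), "n": total.counts}
    ).to_csv(out / "codon_counts.tsv", sep="\t", index=False)

    sites = gen_polymorphism_divergence(config)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    write_vcf(sites, out / "sites.vcf", config.sample_size)

    align_dir = out / "alignments"
    align_dir.mkdir(exist_ok=True)
    rng = config.rng(stream=3)
    F = build_fitness(config.selection_s)
    for k in range(n_alignments):
        a, b = gen_pairwise_alignment(config, F=F, rng=rng)
        (align_dir / f"gene{k:04d}.fa").write_text(
            f">ingroup\n{a}\n>outgroup\n{b}\n"
        )

    tt = gen_trait_tree(config)
    tt.tree.write(path=str(out / "tree.nwk"), schema="newick")
    tt.traits.to_csv(out / "traits.tsv", sep="\t", index_label="tip")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_sites": int(len(sites)),
        "n_alignments": n_alignments,
        "chromosomes": {c: len(s) for c, s in genome.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
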