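"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: two precursor
populations (adipogenic vs myogenic), three animals each contributing one
paired sample per group, negative-binomially distributed counts, and a single
synthetic chromosome carrying known protein-coding genes, known lncRNAs,
planted novel lncRNAs of the intergenic / intronic / antisense classes, and
four decoy kinds (too short, monoexonic low expression, same-strand overlap
with a known gene, long-ORF coding). Planted cis pairs share a latent
per-sample profile so their expression correlates at a target level, and
planted miRNA seed sites (8mer, substituted in place so transcript lengths
are preserved) wire lncRNAs and mRNAs to shared miRNAs.

Everything derives from one integer seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    CANDIDATE,
    KNOWN_LNCRNA,
    KNOWN_MRNA,
    GenomeAnnotation,
    TranscriptModel,
    write_gtf,
)
from .cerna import _norm, _revcomp
from .diffexpr import ExpressionMatrix, GROUP_ADI, GROUP_MYO
from .discovery import builtin_orf_predictor, NONCODING

CHROM = "chrS"

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults reflect the design the pipeline is meant for: a paired 3 vs 3
    comparison, NB dispersion 0.1, planted |log2 fold change| of 2, cis pairs
    at target correlation 0.95, and a moderate annotation (80 coding genes)
    whose library sizes land in the low millions of reads so RPKM values are
    on a realistic scale.
    """

    seed: int = 0
    n_known_mrna: int = 80
    n_known_lnc: int = 10
    n_planted_intergenic: int = 20
    n_planted_intronic: int = 15
    n_planted_antisense: int = 15
    n_decoy_too_short: int = 12
    n_decoy_low_expression: int = 13
    n_decoy_same_strand_overlap: int = 13
    n_decoy_coding: int = 12
    samples_per_group: int = 3
    dispersion: float = 0.1
    de_log2fc: float = 2.0
    n_de_mrna: int = 20
    n_de_lnc: int = 16
    n_cis_pairs: int = 5
    cis_target_r: float = 0.95
    n_mirnas: int = 4
    mirna_wiring: list[tuple[str, str]] | None = None  # (miRNA id, target id)
    animal_sigma: float = 0.2

    def validate(self) -> None:
        counts = [
            self.n_known_mrna, self.n_known_lnc, self.n_planted_intergenic,
            self.n_planted_intronic, self.n_planted_antisense,
            self.n_decoy_too_short, self.n_decoy_low_expression,
            self.n_decoy_same_strand_overlap, self.n_decoy_coding,
            self.n_de_mrna, self.n_de_lnc, self.n_cis_pairs, self.n_mirnas,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all feature counts must be >= 0")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not -1 < self.cis_target_r < 1:
            raise ValueError("cis_target_r must lie in (-1, 1)")
        hosts = (
            self.n_planted_intronic
            + self.n_planted_antisense
            + self.n_decoy_same_strand_overlap
            + self.n_cis_pairs
        )
        if hosts > self.n_known_mrna:
            raise ValueError(
                f"{hosts} host genes required but only {self.n_known_mrna} coding genes"
            )
        if self.n_cis_pairs > self.n_planted_intergenic:
            raise ValueError("cis pairs are planted on intergenic lncRNAs")
        if self.n_de_lnc > self.n_planted_lnc_total:
            raise ValueError("more DE lncRNAs requested than planted lncRNAs")

    @property
    def n_planted_lnc_total(self) -> int:
        return self.n_planted_intergenic + self.n_planted_intronic + self.n_planted_antisense

    @property
    def n_candidates(self) -> int:
        return self.n_planted_lnc_total + (
            self.n_decoy_too_short
            + self.n_decoy_low_expression
            + self.n_decoy_same_strand_overlap
            + self.n_decoy_coding
        )


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus its truth table."""

    config: SimulationConfig
    annotation: GenomeAnnotation  # knowns + candidates
    sequences: dict[str, str]  # transcript id -> spliced sequence
    mirnas: dict[str, str]  # miRNA id -> 5'->3' RNA sequence
    counts: ExpressionMatrix
    truth: pd.DataFrame  # one row per feature
    site_truth: pd.DataFrame  # planted miRNA sites

    @property
    def candidates(self) -> GenomeAnnotation:
        return self.annotation.by_biotype(CANDIDATE)

    @property
    def reference(self) -> GenomeAnnotation:
        return self.annotation.by_biotype(KNOWN_MRNA, KNOWN_LNCRNA)

    @property
    def lengths(self) -> dict[str, int]:
        return {t.id: t.length() for t in self.annotation}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _strip_starts(seq: str) -> str:
    """Remove every ATG (and CAT, its reverse-strand image) so transcripts
    reading this background have no ORF at all."""
    while "ATG" in seq or "CAT" in seq:
        seq = seq.replace("ATG", "AAG").replace("CAT", "CAA")
    return seq


def _coding_sequence(rng: np.random.Generator, length: int, orf_nt: int) -> str:
    """Transcript of ``length`` nt containing one clean ORF of ``orf_nt`` nt
    (ATG..stop inclusive) after a short ATG-free 5' leader."""
    utr5 = 30
    if orf_nt % 3:
        raise ValueError("orf_nt must be a multiple of 3")
    if utr5 + orf_nt > length:
        raise ValueError("transcript too short for requested ORF")
    n_codons = orf_nt // 3 - 2  # minus ATG and stop
    body = "".join(np.array(_CODONS)[rng.integers(0, len(_CODONS), n_codons)])
    lead = _strip_starts(_random_seq(rng, utr5))[:utr5].ljust(utr5, "C")
    tail = _strip_starts(_random_seq(rng, length))[: length - utr5 - orf_nt]
    tail = tail.ljust(length - utr5 - orf_nt, "C")
    return lead + "ATG" + body + "TAA" + tail


class _Genome:
    """Mutable chromosome with transcript-aware extract/paste."""

    def __init__(self, seq: str) -> None:
        self.chars = list(seq)

    def extract(self, t: TranscriptModel) -> str:
        cat = "".join("".join(self.chars[s:e]) for s, e in t.exons)
        return cat if t.strand == "+" else _revcomp(cat)

    def paste(self, t: TranscriptModel, seq: str) -> None:
        if len(seq) != t.length():
            raise ValueError("sequence length must equal exonic length")
        cat = seq if t.strand == "+" else _revcomp(seq)
        pos = 0
        for s, e in t.exons:
            self.chars[s:e] = list(cat[pos : pos + (e - s)])
            pos += e - s


def generate_annotation(
    cfg: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], pd.DataFrame, _Genome]:
    """Lay out the synthetic chromosome and return (annotation, spliced
    sequences, truth frame, genome).

    Planted novel lncRNAs satisfy every discovery filter by construction;
    each decoy kind violates exactly the filter it is named for.
    """
    cfg.validate()
    rng = np.random.default_rng([1, cfg.seed])
    transcripts: list[TranscriptModel] = []
    rows: list[dict] = []
    cursor = 1000

    # host assignments among coding genes
    n_intr, n_anti = cfg.n_planted_intronic, cfg.n_planted_antisense
    n_ovl, n_cis = cfg.n_decoy_same_strand_overlap, cfg.n_cis_pairs
    intronic_hosts = range(0, n_intr)
    antisense_hosts = range(n_intr, n_intr + n_anti)
    overlap_hosts = range(n_intr + n_anti, n_intr + n_anti + n_ovl)
    cis_hosts = range(n_intr + n_anti + n_ovl, n_intr + n_anti + n_ovl + n_cis)

    pending: list[tuple[TranscriptModel, dict]] = []  # candidates, added after knowns

    def add(t: TranscriptModel, **truth) -> None:
        row = {
            "feature_id": t.id,
            "kind": t.biotype,
            "is_novel_lnc": False,
            "lnc_class": "",
            "decoy_kind": "",
            "true_fc": 1.0,
            "is_de": False,
            "cis_partner": "",
            "target_r": np.nan,
            "length": t.length(),
        }
        row.update(truth)
        if t.biotype == CANDIDATE:
            pending.append((t, row))
        else:
            transcripts.append(t)
            rows.append(row)

    def make_exons(start: int, sizes, introns) -> tuple[tuple[int, int], ...]:
        exons = []
        pos = start
        for i, size in enumerate(sizes):
            exons.append((pos, pos + int(size)))
            pos += int(size)
            if i < len(sizes) - 1:
                pos += int(introns[i])
        return tuple(exons)

    cis_lnc_ids: list[str] = []
    cis_gene_ids: list[str] = []

    for g in range(cfg.n_known_mrna):
        n_ex = int(rng.integers(3, 6))
        sizes = rng.integers(160, 301, n_ex)
        introns = rng.integers(800, 3001, n_ex - 1)
        if g in intronic_hosts:
            introns[0] = rng.integers(3500, 6001)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = make_exons(cursor, sizes, introns)
        gid, tid = f"GENE{g:04d}", f"GENE{g:04d}.t1"
        gene = TranscriptModel(tid, gid, CHROM, strand, exons, KNOWN_MRNA)
        add(gene)

        if g in intronic_hosts:
            i0s, i0e = gene.introns[0]
            k = g - intronic_hosts.start
            lstrand = strand if k % 2 == 0 else ("-" if strand == "+" else "+")
            lex = make_exons(i0s + 150, (220, 220), (200,))
            lid = f"CAND_INTRONIC{k:03d}"
            add(
                TranscriptModel(lid, lid, CHROM, lstrand, lex, CANDIDATE),
                is_novel_lnc=True, lnc_class="intronic",
            )
        if g in antisense_hosts:
            k = g - antisense_hosts.start
            e0s, _ = gene.exons[0]
            lstrand = "-" if strand == "+" else "+"
            lex = ((e0s - 520, e0s - 220), (e0s - 80, e0s + 100))
            lid = f"CAND_ANTISENSE{k:03d}"
            add(
                TranscriptModel(lid, lid, CHROM, lstrand, lex, CANDIDATE),
                is_novel_lnc=True, lnc_class="antisense",
            )
        if g in overlap_hosts:
            k = g - overlap_hosts.start
            e0s, _ = gene.exons[0]
            lex = ((e0s - 120, e0s + 140),)
            lid = f"CAND_OVERLAP{k:03d}"
            add(
                TranscriptModel(lid, lid, CHROM, strand, lex, CANDIDATE),
                decoy_kind="same_strand_overlap",
            )

        cursor = gene.end
        if g in cis_hosts:
            k = g - cis_hosts.start
            d = int(rng.integers(15_000, 40_001))
            lstrand = "+" if rng.random() < 0.5 else "-"
            lex = make_exons(cursor + d, (260, 260), (400,))
            lid = f"CAND_CIS{k:03d}"
            add(
                TranscriptModel(lid, lid, CHROM, lstrand, lex, CANDIDATE),
                is_novel_lnc=True, lnc_class="intergenic",
                cis_partner=gid, target_r=cfg.cis_target_r,
            )
            cis_lnc_ids.append(lid)
            cis_gene_ids.append(gid)
            cursor = lex[-1][1] + int(rng.integers(5000, 10_001))
        else:
            cursor += int(rng.integers(8000, 25_001))

    for k in range(cfg.n_known_lnc):
        sizes = rng.integers(200, 501, 2)
        exons = make_exons(cursor, sizes, rng.integers(400, 1500, 1))
        strand = "+" if rng.random() < 0.5 else "-"
        lid = f"KNLNC{k:03d}"
        add(TranscriptModel(lid, lid, CHROM, strand, exons, KNOWN_LNCRNA))
        cursor = exons[-1][1] + int(rng.integers(4000, 9001))

    def place_intergenic(lid: str, sizes, introns, **truth) -> None:
        nonlocal cursor
        strand = "+" if rng.random() < 0.5 else "-"
        exons = make_exons(cursor, sizes, introns)
        add(TranscriptModel(lid, lid, CHROM, strand, exons, CANDIDATE), **truth)
        cursor = exons[-1][1] + int(rng.integers(2000, 8001))

    n_free_intergenic = cfg.n_planted_intergenic - cfg.n_cis_pairs
    for k in range(n_free_intergenic):
        n_ex = int(rng.integers(2, 4))
        place_intergenic(
            f"CAND_INTERGENIC{k:03d}",
            rng.integers(150, 401, n_ex),
            rng.integers(300, 1501, n_ex - 1),
            is_novel_lnc=True, lnc_class="intergenic",
        )
    for k in range(cfg.n_decoy_too_short):
        place_intergenic(
            f"CAND_SHORT{k:03d}", [int(rng.integers(80, 181))], [],
            decoy_kind="too_short",
        )
    for k in range(cfg.n_decoy_low_expression):
        place_intergenic(
            f"CAND_LOWEXPR{k:03d}", [450], [], decoy_kind="low_expression",
        )
    for k in range(cfg.n_decoy_coding):
        place_intergenic(
            f"CAND_CODING{k:03d}", (300, 300), [int(rng.integers(300, 1201))],
            decoy_kind="coding",
        )

    for t, row in pending:
        transcripts.append(t)
        rows.append(row)
    ann = GenomeAnnotation(transcripts)
    truth = pd.DataFrame(rows).set_index("feature_id", drop=False)

    # DE assignment: alternate up/down over DE mRNAs and DE lncRNAs. Cis-pair
    # members are left at FC 1: their strong shared per-sample covariation
    # (needed to realize the target correlation at n = 6) would otherwise
    # drown the 3 vs 3 group signal, and the two planted effects are meant to
    # probe different pipeline stages.
    fc_hi, fc_lo = 2.0**cfg.de_log2fc, 2.0**-cfg.de_log2fc
    free_genes = [
        f"GENE{g:04d}" for g in range(cfg.n_known_mrna)
        if g not in cis_hosts
    ]
    de_mrnas = free_genes[: cfg.n_de_mrna]
    planted_ids = list(truth.index[truth["is_novel_lnc"]])
    de_lncs = [i for i in planted_ids if i not in cis_lnc_ids][: cfg.n_de_lnc]
    for i, gid in enumerate(de_mrnas):
        tid = f"{gid}.t1"
        truth.loc[tid, ["true_fc", "is_de"]] = (fc_hi if i % 2 == 0 else fc_lo, True)
    for i, lid in enumerate(de_lncs):
        truth.loc[lid, ["true_fc", "is_de"]] = (fc_hi if i % 2 == 0 else fc_lo, True)
    for lid, gid in zip(cis_lnc_ids, cis_gene_ids):
        truth.loc[f"{gid}.t1", ["cis_partner", "target_r"]] = (lid, cfg.cis_target_r)

    # chromosome sequence: ORF-free background, then coding sequences pasted in
    genome = _Genome(_strip_starts(_random_seq(rng, cursor + 1000)))
    for t in ann:
        if t.biotype == KNOWN_MRNA or truth.loc[t.id, "decoy_kind"] == "coding":
            L = t.length()
            genome.paste(t, _coding_sequence(rng, L, 3 * ((L - 40) // 3)))
    sequences = {t.id: genome.extract(t) for t in ann}
    return ann, sequences, truth, genome


def plant_mirna_sites(
    cfg: SimulationConfig,
    ann: GenomeAnnotation,
    sequences: dict[str, str],
    truth: pd.DataFrame,
    genome: _Genome,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate miRNAs and substitute exact 8mer seed sites into wired targets.

    Substitution preserves transcript length; a planted lncRNA whose coding
    call would flip is re-planted at another position. Returns the miRNA
    sequences and the planted-site truth table; ``sequences`` and ``genome``
    are updated in place.
    """
    rng = np.random.default_rng([3, cfg.seed])
    mirnas: dict[str, str] = {}
    seeds_seen = set()
    while len(mirnas) < cfg.n_mirnas:
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 22)])
        if seq[1:8] in seeds_seen:
            continue
        seeds_seen.add(seq[1:8])
        mirnas[f"miR-{len(mirnas) + 1:03d}"] = seq

    wiring = cfg.mirna_wiring
    if wiring is None:
        lnc_pool = [
            i for i in truth.index
            if truth.loc[i, "lnc_class"] == "intergenic"
        ]
        # only genes whose exons are not shared with any candidate: planting a
        # site must not rewrite a planted lncRNA's sequence behind its back
        n_hosts = (
            cfg.n_planted_intronic + cfg.n_planted_antisense
            + cfg.n_decoy_same_strand_overlap + cfg.n_cis_pairs
        )
        gene_pool = [f"GENE{g:04d}.t1" for g in range(n_hosts, cfg.n_known_mrna)]
        wiring = []
        mids = list(mirnas)
        for k, mid in enumerate(mids):
            if lnc_pool:
                wiring.append((mid, lnc_pool[k % len(lnc_pool)]))
            for j in range(2):
                if gene_pool:
                    wiring.append((mid, gene_pool[(2 * k + j) % len(gene_pool)]))

    site_rows = []
    for mid, target in wiring:
        if target not in sequences:
            raise KeyError(f"wired target {target} has no sequence")
        site = _revcomp(_norm(mirnas[mid])[1:8]) + "A"
        t = ann[target]
        seq = sequences[target]
        if len(seq) < 40:
            raise ValueError(f"target {target} too short for a seed site")
        is_planted_lnc = bool(truth.loc[target, "is_novel_lnc"])
        for _ in range(30):
            pos = int(rng.integers(10, len(seq) - 10 - len(site)))
            new = seq[:pos] + site + seq[pos + len(site):]
            if not is_planted_lnc or builtin_orf_predictor(new).label == NONCODING:
                break
        else:
            raise RuntimeError(f"could not plant a safe site in {target}")
        sequences[target] = new
        genome.paste(t, new)
        site_rows.append(
            {"mirna_id": mid, "target_id": target, "position": pos, "site_type": "8mer"}
        )
    site_truth = pd.DataFrame(
        site_rows, columns=["mirna_id", "target_id", "position", "site_type"]
    )
    # overlapping transcripts may share bases with a planted region: refresh
    for t in ann:
        sequences[t.id] = genome.extract(t)
    return mirnas, site_truth


def simulate_counts(
    cfg: SimulationConfig,
    ann: GenomeAnnotation,
    truth: pd.DataFrame,
    seed: int | None = None,
) -> ExpressionMatrix:
    """NB counts for every feature across the paired two-group design.

    mean_ij = base_i · FC_i^[j in Myo] · animal_j · exp(σ_b · w_ij), counts ~
    NB(mean, dispersion). ``w`` is i.i.d. biological noise except for planted
    cis pairs, which draw it from a shared latent profile mixed to the target
    correlation. ``seed`` overrides the config seed stream (used for replicate
    studies on one annotation).
    """
    rng = np.random.default_rng([4, cfg.seed if seed is None else seed])
    n = cfg.samples_per_group
    samples = [f"Adi_{a+1}" for a in range(n)] + [f"Myo_{a+1}" for a in range(n)]
    sheet = pd.DataFrame(
        {
            "group": [GROUP_ADI] * n + [GROUP_MYO] * n,
            "animal": list(range(1, n + 1)) * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    feats = [t.id for t in ann]
    base = np.empty(len(feats))
    for i, f in enumerate(feats):
        kind = truth.loc[f, "kind"]
        if truth.loc[f, "decoy_kind"] == "low_expression":
            base[i] = rng.uniform(0.02, 0.12)
        elif kind == KNOWN_MRNA:
            base[i] = rng.lognormal(np.log(20_000), 1.0)
        elif kind == KNOWN_LNCRNA:
            base[i] = rng.lognormal(np.log(2_000), 0.8)
        else:
            base[i] = rng.lognormal(np.log(500), 0.6)

    fc = truth.loc[feats, "true_fc"].to_numpy(dtype=float)
    is_myo = np.array([0] * n + [1] * n)
    animal_fac = rng.lognormal(0.0, cfg.animal_sigma, n)
    animal_fac = np.concatenate([animal_fac, animal_fac])

    # Shared latent profile for cis pairs only; all other features are pure NB
    # around base·FC·animal, matching the DE caller's model. Each pair member
    # shares one standard-normal profile z, with per-member amplitude
    # σ_i² = ρ·u_i/(1−ρ), where u_i ≈ dispersion + 1/base_i is the member's
    # residual log-scale noise — this makes the pair's log-expression
    # correlation equal the target ρ in expectation.
    latent = np.zeros((len(feats), 2 * n))
    rho = abs(cfg.cis_target_r)
    sgn = float(np.sign(cfg.cis_target_r)) or 1.0
    idx = {f: i for i, f in enumerate(feats)}
    for f in feats:
        partner = truth.loc[f, "cis_partner"]
        if partner == "" or truth.loc[f, "kind"] != KNOWN_MRNA:
            continue
        # f is the coding gene's transcript; partner is its lncRNA
        gi, li = idx[f], idx[partner]
        z = rng.standard_normal(2 * n)
        for row, sign, i in ((li, 1.0, li), (gi, sgn, gi)):
            u = cfg.dispersion + 1.0 / max(base[i], 1e-6)
            sigma = np.sqrt(rho * u / (1 - rho))
            latent[row] = sign * sigma * z

    mu = (
        base[:, None]
        * np.power(fc[:, None], is_myo[None, :])
        * animal_fac[None, :]
        * np.exp(latent)
    )
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    values = pd.DataFrame(counts, index=pd.Index(feats, name="feature_id"), columns=samples)
    return ExpressionMatrix(values=values, sample_sheet=sheet, unit="counts")


def simulate_null_matrix(
    n_features: int = 2000,
    samples_per_group: int = 3,
    dispersion: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Pure null NB matrix (identical group means) for calibration checks."""
    rng = np.random.default_rng([5, seed])
    n = samples_per_group
    samples = [f"Adi_{a+1}" for a in range(n)] + [f"Myo_{a+1}" for a in range(n)]
    sheet = pd.DataFrame(
        {"group": [GROUP_ADI] * n + [GROUP_MYO] * n, "animal": list(range(1, n + 1)) * 2},
        index=pd.Index(samples, name="sample"),
    )
    mu = rng.lognormal(np.log(200), 1.0, n_features)
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p[:, None], (n_features, 2 * n))
    values = pd.DataFrame(
        counts,
        index=pd.Index([f"F{i:05d}" for i in range(n_features)], name="feature_id"),
        columns=samples,
    )
    return ExpressionMatrix(values=values, sample_sheet=sheet, unit="counts")


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Run all three generator stages and bundle the result."""
    cfg = cfg or SimulationConfig()
    ann, sequences, truth, genome = generate_annotation(cfg)
    mirnas, site_truth = plant_mirna_sites(cfg, ann, sequences, truth, genome)
    counts = simulate_counts(cfg, ann, truth)
    return SyntheticDataset(
        config=cfg,
        annotation=ann,
        sequences=sequences,
        mirnas=mirnas,
        counts=counts,
        truth=truth,
        site_truth=site_truth,
    )


def _write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def make_term_map(truth: pd.DataFrame, n_background_terms: int = 6) -> pd.DataFrame:
    """Gene → term annotation over the coding genes, with the planted DE genes
    loaded into two dedicated terms (up/down) so enrichment has real signal."""
    gene_rows = truth[truth["kind"] == KNOWN_MRNA]
    rows = []
    for i, (tid, row) in enumerate(gene_rows.iterrows()):
        gid = tid.rsplit(".", 1)[0]
        rows.append((gid, f"TERM_{i % n_background_terms:02d}"))
        if row["is_de"]:
            rows.append((gid, "TERM_DE_UP" if row["true_fc"] > 1 else "TERM_DE_DOWN"))
    return pd.DataFrame(rows, columns=["gene", "term"])


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write GTFs, FASTAs, counts + sample sheet, term map and truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": out / "reference.gtf",
        "candidates_gtf": out / "candidates.gtf",
        "transcripts_fasta": out / "transcripts.fa",
        "mirna_fasta": out / "mirnas.fa",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "term_map": out / "terms.tsv",
        "truth": out / "truth.tsv",
        "sites": out / "sites.tsv",
    }
    write_gtf(ds.reference, paths["reference_gtf"])
    write_gtf(ds.candidates, paths["candidates_gtf"])
    _write_fasta(ds.sequences, paths["transcripts_fasta"])
    _write_fasta(ds.mirnas, paths["mirna_fasta"])
    ds.counts.to_tsv(paths["counts"], paths["samples"])
    make_term_map(ds.truth).to_csv(paths["term_map"], sep="\t", header=False, index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    ds.site_truth.to_csv(paths["sites"], sep="\t", index=False)
    return paths
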