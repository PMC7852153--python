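"""Cis-target inference for differentially expressed lncRNAs.

A cis target is a protein-coding gene that either overlaps the lncRNA
(exonic overlap or gene-body containment) or lies within a genomic window of
it, and whose expression correlates with the lncRNA across samples with
|Pearson r| strictly greater than a threshold (default 0.6). An optional
homology screen (blastn-style ungapped local alignment with Karlin–Altschul
E-values) can pre-filter pairs by sequence similarity.

The window lower bound defaults to 0 rather than 10 kb: reported cis pairs
routinely include overlapping, intronic and sub-10-kb neighbours, so a strict
lower bound would contradict the relations this method is expected to return.
Both bounds are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    KNOWN_MRNA,
    GenomeAnnotation,
    GenomicRelation,
    RelationKind,
    TranscriptModel,
    genomic_relation,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CisTargetPair:
    """An accepted lncRNA–gene pair with its genomic relation and Pearson r."""

    lncrna_id: str
    gene_id: str
    relation: GenomicRelation
    r: float
    lnc_fold_change: float | None = None
    gene_fold_change: float | None = None


def find_neighbor_genes(
    lnc: TranscriptModel,
    ref: GenomeAnnotation,
    window_max: int = 100_000,
    window_min: int = 0,
    orientation: str = "gene",
) -> list[tuple[str, GenomicRelation]]:
    """Protein-coding genes overlapping the lncRNA or whose span gap to it lies
    in [window_min, window_max], each with its :class:`GenomicRelation`.

    A gene's relation is the closest relation over its transcripts
    (overlap > intron > smallest gap).
    """
    hits: dict[str, GenomicRelation] = {}
    rank = {RelationKind.OVERLAP: 0, RelationKind.INTRON: 1}
    for t in ref.overlapping(lnc.chrom, lnc.start - window_max, lnc.end + window_max):
        if t.biotype != KNOWN_MRNA:
            continue
        rel = genomic_relation(lnc, t, orientation=orientation)
        if rel is None:
            continue
        if rel.kind in (RelationKind.UPSTREAM, RelationKind.DOWNSTREAM):
            if not (window_min <= rel.distance_bp <= window_max):
                continue
        cur = hits.get(t.gene_id)
        key = (rank.get(rel.kind, 2), rel.distance_bp)
        if cur is None or key < (rank.get(cur.kind, 2), cur.distance_bp):
            hits[t.gene_id] = rel
    return sorted(hits.items())


def pearson_r(x, y) -> float | None:
    """Product-moment correlation; ``None`` when either vector has zero
    variance (the pair is skipped and logged by callers)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


# --- homology screen ---------------------------------------------------------

_COMP = str.maketrans("ACGTU", "TGCAA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HomologyMatch:
    """Best ungapped local match between two sequences."""

    query_start: int
    subject_start: int
    length: int
    matches: int
    score: int
    evalue: float
    strand: str  # '+' or '-'

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def _best_ungapped_match(
    q: str, s: str, k: int, match: int, mismatch: int
) -> tuple[int, int, int, int, int]:
    """Best-scoring ungapped extension over k-mer anchors.

    Returns (q_start, s_start, length, matches, score) of the best local
    segment, or zeros when no anchor exists.
    """
    anchors: dict[str, list[int]] = {}
    for i in range(len(q) - k + 1):
        anchors.setdefault(q[i : i + k], []).append(i)
    best = (0, 0, 0, 0, 0)
    seen: set[tuple[int, int]] = set()
    for j in range(len(s) - k + 1):
        for i in anchors.get(s[j : j + k], ()):
            # extend left
            li, lj = i, j
            while li > 0 and lj > 0 and q[li - 1] == s[lj - 1]:
                li -= 1
                lj -= 1
            if (li, lj) in seen:
                continue
            seen.add((li, lj))
            # scan right from the maximal-left start, tracking best prefix score
            score = 0
            matches = 0
            best_here = (0, 0)  # (score, length)
            best_matches = 0
            x, y = li, lj
            length = 0
            while x < len(q) and y < len(s):
                if q[x] == s[y]:
                    score += match
                    matches += 1
                else:
                    score += mismatch
                length += 1
                if score > best_here[0]:
                    best_here = (score, length)
                    best_matches = matches
                if score < best_here[0] - 20:  # X-drop
                    break
                x += 1
                y += 1
            if best_here[0] > best[4] or (
                best_here[0] == best[4] and best_here[1] > best[2]
            ):
                best = (li, lj, best_here[1], best_matches, best_here[0])
    return best


def homology_screen(
    lnc_seq: str,
    gene_seq: str,
    min_identity: float = 0.99,
    min_len: int = 20,
    max_evalue: float = 1e-10,
    k: int = 11,
    match: int = 1,
    mismatch: int = -2,
    karlin_k: float = 0.71,
    karlin_lambda: float = 1.37,
) -> tuple[bool, HomologyMatch | None]:
    """Sequence-homology pre-filter for a lncRNA–gene pair.

    k-mer-anchored ungapped extension on both strands; the best local match
    passes when its E-value < ``max_evalue``, identity > ``min_identity`` and
    length ≥ ``min_len`` (all three must hold). E-values use the Karlin–
    Altschul formula E = K·m·n·exp(−λ·S) with standard nucleotide parameters.
    """
    if not lnc_seq or not gene_seq:
        raise ValueError("homology_screen requires non-empty sequences")
    q = lnc_seq.upper().replace("U", "T")
    s = gene_seq.upper().replace("U", "T")
    candidates = []
    for strand, query in (("+", q), ("-", _revcomp(q))):
        qs, ss, length, matches, score = _best_ungapped_match(query, s, k, match, mismatch)
        if length:
            ev = karlin_k * len(q) * len(s) * math.exp(-karlin_lambda * score)
            candidates.append(HomologyMatch(qs, ss, length, matches, score, ev, strand))
    if not candidates:
        return False, None
    best = min(candidates, key=lambda h: (h.evalue, -h.score))
    ok = (
        best.evalue < max_evalue
        and best.identity > min_identity
        and best.length >= min_len
    )
    return ok, best


# --- the cis-target call -----------------------------------------------------


def call_cis_targets(
    de_lncrnas: GenomeAnnotation,
    ref: GenomeAnnotation,
    expr,
    r_min: float = 0.6,
    window_max: int = 100_000,
    window_min: int = 0,
    fold_changes: pd.Series | None = None,
    sequences=None,
    use_homology: bool = False,
    orientation: str = "gene",
) -> list[CisTargetPair]:
    """Identify cis target genes of DE lncRNAs.

    For each lncRNA, neighbour protein-coding genes from
    :func:`find_neighbor_genes` are tested for expression correlation across
    all samples of ``expr`` (RPKM by convention; gene expression rows are keyed
    by gene id); pairs with |r| strictly greater than ``r_min`` are accepted.
    When ``use_homology`` is set, pairs must additionally pass
    :func:`homology_screen` on the supplied ``sequences``.
    """
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "samples") else expr
    pairs: list[CisTargetPair] = []
    for lnc in de_lncrnas:
        if lnc.id not in values.index:
            raise KeyError(f"lncRNA {lnc.id} has no expression row")
        x = values.loc[lnc.id].to_numpy(dtype=float)
        for gene_id, rel in find_neighbor_genes(
            lnc, ref, window_max=window_max, window_min=window_min, orientation=orientation
        ):
            if gene_id in values.index:
                y = values.loc[gene_id].to_numpy(dtype=float)
            else:
                # gene-level expression = sum over the gene's transcript rows
                tx = [t.id for t in ref.gene_transcripts(gene_id) if t.id in values.index]
                if not tx:
                    raise KeyError(f"gene {gene_id} has no expression row")
                y = values.loc[tx].sum(axis=0).to_numpy(dtype=float)
            if use_homology:
                if sequences is None:
                    raise ValueError("use_homology requires sequences")
                ok, _ = homology_screen(sequences[lnc.id], sequences[gene_id])
                if not ok:
                    continue
            r = pearson_r(x, y)
            if r is None:
                logger.info("pair %s/%s skipped: zero variance", lnc.id, gene_id)
                continue
            if abs(r) > r_min:
                pairs.append(
                    CisTargetPair(
                        lncrna_id=lnc.id,
                        gene_id=gene_id,
                        relation=rel,
                        r=r,
                        lnc_fold_change=(
                            float(fold_changes[lnc.id])
                            if fold_changes is not None and lnc.id in fold_changes
                            else None
                        ),
                        gene_fold_change=(
                            float(fold_changes[gene_id])
                            if fold_changes is not None and gene_id in fold_changes
                            else None
                        ),
                    )
                )
    return pairs


def cis_table(pairs: list[CisTargetPair]) -> pd.DataFrame:
    """Tabular view: lncRNA, lnc FC, gene, gene FC, relationship string
    ('Overlap'/'Intron'/'Upstream:<d>'/'Downstream:<d>'), correlation index."""
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "lnc_fold_change": [p.lnc_fold_change for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "gene_fold_change": [p.gene_fold_change for p in pairs],
            "relationship": [str(p.relation) for p in pairs],
            "correlation_index": [round(p.r, 4) for p in pairs],
        }
    )
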