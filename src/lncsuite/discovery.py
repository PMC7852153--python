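"""Novel-lncRNA discovery: a four-stage filter cascade plus a multi-predictor
noncoding consensus.

The cascade mirrors the standard workflow for calling lncRNAs from assembled
transcripts: collapse replicate structures, drop short transcripts (< 200 nt),
drop 'background' transcripts (weak, single-sample or monoexonic), drop
candidates overlapping known genes on the same strand, then keep only
transcripts every coding-potential predictor labels noncoding.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .annotation import (
    CANDIDATE,
    GenomeAnnotation,
    classify_candidate,
    deduplicate_transcripts,
    exonic_overlap,
)

CODING = "coding"
NONCODING = "noncoding"

#: conventional lncRNA-calling defaults for the built-in ORF heuristic
#: (not taken from any particular study)
DEFAULT_MIN_ORF_NT = 300
DEFAULT_MIN_ORF_COVERAGE = 0.5

_STOPS = {"TAA", "TAG", "TGA"}
_VALID_CHARS = re.compile(r"^[ACGTUN]*$")


@dataclass(frozen=True)
class CodingPotentialCall:
    """One predictor's verdict on one transcript."""

    transcript_id: str
    predictor: str
    label: str  # coding | noncoding
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (CODING, NONCODING):
            raise ValueError(f"label must be coding/noncoding, got {self.label!r}")


@dataclass
class FilterReport:
    """Audit trail of the cascade: for each transcript, the first rule that
    removed it (or None for survivors), in rule application order."""

    failed: dict[str, str] = field(default_factory=dict)
    rules: list[str] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def record_rule(self, rule: str, removed: Iterable[str]) -> None:
        self.rules.append(rule)
        for tid in removed:
            self.failed.setdefault(tid, rule)

    def failure_rule(self, tid: str) -> str | None:
        return self.failed.get(tid)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(set(self.failed) | set(self.survivors))
        return pd.DataFrame(
            {
                "transcript_id": ids,
                "status": ["removed" if i in self.failed else "kept" for i in ids],
                "failed_rule": [self.failed.get(i, "") for i in ids],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --- individual filters ------------------------------------------------------


def filter_by_length(
    candidates: GenomeAnnotation, min_len: int = 200, report: FilterReport | None = None
) -> GenomeAnnotation:
    """Remove transcripts whose total exonic length is below ``min_len``
    (boundary value kept)."""
    keep, drop = [], []
    for t in candidates:
        (keep if t.length() >= min_len else drop).append(t.id)
    if report is not None:
        report.record_rule("length", drop)
    return candidates.subset(keep)


def filter_background(
    candidates: GenomeAnnotation,
    expr,
    min_max_expr: float = 2.0,
    min_samples: int = 2,
    min_exons: int = 2,
    mode: str = "conjunctive",
    report: FilterReport | None = None,
) -> GenomeAnnotation:
    """Remove 'background' transcripts.

    A transcript is weak when its maximal expression across samples is strictly
    below ``min_max_expr``; it is sparse when detected (expression > 0) in fewer
    than ``min_samples`` samples or has fewer than ``min_exons`` exons. The
    default ``conjunctive`` mode removes a transcript only when it is weak AND
    sparse; ``disjunctive`` removes it when either holds. ``expr`` is an
    :class:`~lncsuite.diffexpr.ExpressionMatrix` (RPKM by convention) or a
    feature × sample DataFrame.
    """
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"mode must be conjunctive/disjunctive, got {mode!r}")
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "samples") else expr
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expr must be an ExpressionMatrix or a DataFrame")
    missing = [t.id for t in candidates if t.id not in values.index]
    if missing:
        raise KeyError(f"candidates missing from expression matrix: {missing}")
    keep, drop = [], []
    for t in candidates:
        row = values.loc[t.id]
        weak = row.max() < min_max_expr
        sparse = int((row > 0).sum()) < min_samples or t.n_exons < min_exons
        removed = (weak and sparse) if mode == "conjunctive" else (weak or sparse)
        (drop if removed else keep).append(t.id)
    if report is not None:
        report.record_rule("background", drop)
    return candidates.subset(keep)


def remove_known_overlaps(
    candidates: GenomeAnnotation,
    ref: GenomeAnnotation,
    report: FilterReport | None = None,
) -> GenomeAnnotation:
    """Discard candidates with same-strand exonic overlap with any known mRNA
    or lncRNA; antisense overlap is retained."""
    keep, drop = [], []
    for t in candidates:
        hits = [
            k
            for k in ref.overlapping(t.chrom, t.start, t.end, strand=t.strand)
            if k.biotype != CANDIDATE and exonic_overlap(t, k)
        ]
        (drop if hits else keep).append(t.id)
    if report is not None:
        report.record_rule("known_overlap", drop)
    return candidates.subset(keep)


# --- coding potential --------------------------------------------------------


def longest_orf(seq: str) -> int:
    """Length in nt of the longest forward-strand ORF (ATG through stop codon,
    any of the three frames), 0 if none."""
    s = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def builtin_orf_predictor(
    seq: str,
    transcript_id: str = "",
    min_orf_nt: int = DEFAULT_MIN_ORF_NT,
    min_coverage: float = DEFAULT_MIN_ORF_COVERAGE,
) -> CodingPotentialCall:
    """Built-in ORF heuristic: coding iff the longest ORF is at least
    ``min_orf_nt`` long OR covers at least ``min_coverage`` of the transcript.

    Score is the longest ORF length. Pluggable alongside external predictor
    calls loaded from a tab-delimited file (:func:`read_predictor_calls`).
    """
    s = seq.upper().replace("U", "T")
    if not _VALID_CHARS.match(s):
        bad = sorted(set(s) - set("ACGTUN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    if not s or set(s) == {"N"}:
        return CodingPotentialCall(transcript_id, "orf", NONCODING, 0.0)
    orf = longest_orf(s)
    coding = orf >= min_orf_nt or orf / len(s) >= min_coverage
    return CodingPotentialCall(transcript_id, "orf", CODING if coding else NONCODING, float(orf))


def read_predictor_calls(path) -> list[CodingPotentialCall]:
    """Load external predictor output: tab-delimited
    (transcript_id, predictor, label, score)."""
    df = pd.read_csv(
        path, sep="\t", names=["transcript_id", "predictor", "label", "score"],
        header=None, comment="#",
    )
    if df.iloc[0]["transcript_id"] == "transcript_id":  # tolerate a header row
        df = df.iloc[1:]
    return [
        CodingPotentialCall(r.transcript_id, r.predictor, r.label, float(r.score))
        for r in df.itertuples()
    ]


def consensus_noncoding(calls: Iterable[CodingPotentialCall]) -> str:
    """'lncRNA' iff every predictor labels the transcript noncoding (the
    Venn-intersection rule), else 'rejected'. Raises on an empty call set."""
    calls = list(calls)
    if not calls:
        raise ValueError("cannot classify a transcript with zero predictor calls")
    return "lncRNA" if all(c.label == NONCODING for c in calls) else "rejected"


# --- full cascade ------------------------------------------------------------


@dataclass
class DiscoveryResult:
    survivors: GenomeAnnotation
    report: FilterReport
    class_counts: Counter
    classes: dict[str, str]


def discover_lncrnas(
    candidates: GenomeAnnotation,
    ref: GenomeAnnotation,
    expr,
    sequences: Mapping[str, str] | None = None,
    predictors: list[Callable[[str, str], CodingPotentialCall]] | None = None,
    external_calls: Iterable[CodingPotentialCall] = (),
    min_len: int = 200,
    min_max_expr: float = 2.0,
    min_samples: int = 2,
    min_exons: int = 2,
    background_mode: str = "conjunctive",
) -> DiscoveryResult:
    """Run the full cascade: deduplicate → length → background → known-strand
    overlap → noncoding consensus; classify survivors into genomic classes.

    ``predictors`` are callables ``f(seq, transcript_id) -> CodingPotentialCall``
    applied to ``sequences``; defaults to the built-in ORF heuristic when
    sequences are supplied. ``external_calls`` merge in file-based predictor
    output (e.g. CPC/CNCI/Pfam runs done elsewhere).
    """
    report = FilterReport()
    ann = deduplicate_transcripts(candidates)
    report.record_rule("duplicate", set(t.id for t in candidates) - set(t.id for t in ann))
    ann = filter_by_length(ann, min_len=min_len, report=report)
    ann = filter_background(
        ann, expr, min_max_expr=min_max_expr, min_samples=min_samples,
        min_exons=min_exons, mode=background_mode, report=report,
    )
    ann = remove_known_overlaps(ann, ref, report=report)

    by_tx: dict[str, list[CodingPotentialCall]] = {}
    for c in external_calls:
        by_tx.setdefault(c.transcript_id, []).append(c)
    if sequences is not None:
        preds = predictors if predictors is not None else [
            lambda seq, tid: builtin_orf_predictor(seq, tid)
        ]
        for t in ann:
            if t.id not in sequences:
                raise KeyError(f"no sequence provided for candidate {t.id}")
            for p in preds:
                by_tx.setdefault(t.id, []).append(p(sequences[t.id], t.id))
    keep, drop = [], []
    for t in ann:
        calls = by_tx.get(t.id, [])
        if not calls:
            raise ValueError(f"no coding-potential calls for transcript {t.id}")
        (keep if consensus_noncoding(calls) == "lncRNA" else drop).append(t.id)
    report.record_rule("coding_potential", drop)
    survivors = ann.subset(keep)
    report.survivors = sorted(keep)

    classes = {t.id: classify_candidate(t, ref) for t in survivors}
    return DiscoveryResult(
        survivors=survivors,
        report=report,
        class_counts=Counter(classes.values()),
        classes=classes,
    )
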