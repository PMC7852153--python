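"""Stage orchestration: discover → de → cis → cerna → enrich.

Each stage reads its inputs, writes tab-delimited outputs into the configured
output directory, and logs the parameters it ran with. The summary report is
recomputed from the written output files rather than from in-memory
bookkeeping, so the report always reflects what is on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from .annotation import GenomeAnnotation, read_gtf, write_bed6, write_gtf
from .cerna import build_cerna_network, export_network, scan_targets, write_site_table, SITE_TYPES
from .cis import call_cis_targets, cis_table
from .diffexpr import (
    ExpressionMatrix,
    call_de,
    compute_rpkm,
    de_summary,
    nb_wald_test,
    size_factors,
    write_de_table,
)
from .discovery import discover_lncrnas, read_predictor_calls
from .enrichment import enrichment_table, hypergeometric_enrichment, read_term_map
from .simulate import _write_fasta

logger = logging.getLogger(__name__)

STAGES = ("discover", "de", "cis", "cerna", "enrich")


@dataclass
class PipelineConfig:
    """Paths and stage parameters; defaults are the standard thresholds
    (200 nt length, max expression 2.0, fold change 2 / 0.5 at FDR 0.05,
    100 kb window, |r| > 0.6, blastn-style homology triple)."""

    # inputs
    reference_gtf: str = ""
    candidates_gtf: str = ""
    counts: str = ""
    samples: str = ""
    transcripts_fasta: str = ""
    mirna_fasta: str = ""
    term_map: str = ""
    predictor_calls: str = ""
    outdir: str = "lncsuite_out"
    seed: int = 0
    # discovery
    min_len: int = 200
    min_max_expr: float = 2.0
    min_samples: int = 2
    min_exons: int = 2
    background_mode: str = "conjunctive"
    # DE
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    # cis
    window_max: int = 100_000
    window_min: int = 0
    r_min: float = 0.6
    use_homology: bool = False
    min_identity: float = 0.99
    min_match_len: int = 20
    max_evalue: float = 1e-10
    orientation: str = "gene"
    # ceRNA
    site_types: tuple = SITE_TYPES
    # enrichment
    enrich_alpha: float = 0.05

    def validate(self) -> None:
        if self.window_min < 0 or self.window_max < 0:
            raise ValueError("genomic windows must be non-negative")
        if self.window_min > self.window_max:
            raise ValueError("window_min must not exceed window_max")
        if self.min_len < 0:
            raise ValueError("min_len must be non-negative")
        if not 0 < self.alpha < 1 or not 0 < self.enrich_alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_up < 1 or not 0 < self.fc_down <= 1:
            raise ValueError("fold-change thresholds must bracket 1")
        if self.r_min < 0 or self.r_min >= 1:
            raise ValueError("r_min must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "site_types" in data:
            data["site_types"] = tuple(data["site_types"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["site_types"] = list(data["site_types"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_fasta(path) -> dict[str, str]:
    """FASTA → id → sequence (id = first whitespace token)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _require(cfg: PipelineConfig, stage: str, **paths) -> None:
    missing = [
        f"{name} ({path!r})"
        for name, path in paths.items()
        if not path or not Path(path).exists()
    ]
    if missing:
        raise FileNotFoundError(f"stage {stage!r} missing inputs: {', '.join(missing)}")


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the selected stages in canonical order and write a summary.

    Returns the summary dict (also written as ``summary.json``/``report.txt``
    in the output directory). Stage outputs:

    - discover: ``novel_lncrnas.gtf/.fa/.bed``, ``filter_report.tsv``
    - de: ``de_results.tsv`` (all features, with direction calls)
    - cis: ``cis_targets.tsv``
    - cerna: ``cerna_network.sif``, ``cerna_network.graphml``, ``mirna_sites.tsv``
    - enrich: ``enrichment.tsv``
    """
    cfg.validate()
    selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # validate inputs for every selected stage before doing any work
    for stage in selected:
        if stage == "discover":
            _require(cfg, stage, reference_gtf=cfg.reference_gtf,
                     candidates_gtf=cfg.candidates_gtf, counts=cfg.counts,
                     samples=cfg.samples, transcripts_fasta=cfg.transcripts_fasta)
        elif stage == "de":
            _require(cfg, stage, counts=cfg.counts, samples=cfg.samples)
        elif stage == "cis":
            _require(cfg, stage, reference_gtf=cfg.reference_gtf, counts=cfg.counts,
                     samples=cfg.samples)
        elif stage == "cerna":
            _require(cfg, stage, mirna_fasta=cfg.mirna_fasta,
                     transcripts_fasta=cfg.transcripts_fasta)
        elif stage == "enrich":
            _require(cfg, stage, term_map=cfg.term_map)

    ref = read_gtf(cfg.reference_gtf) if cfg.reference_gtf else None
    candidates = read_gtf(cfg.candidates_gtf) if cfg.candidates_gtf else None
    counts = (
        ExpressionMatrix.from_tsv(cfg.counts, cfg.samples)
        if cfg.counts and Path(cfg.counts).exists()
        else None
    )
    sequences = read_fasta(cfg.transcripts_fasta) if cfg.transcripts_fasta else {}

    lengths: dict[str, int] = {}
    for source in (ref, candidates):
        if source is not None:
            lengths.update({t.id: t.length() for t in source})
    rpkm = None
    if counts is not None and lengths:
        known_lengths = {f: lengths.get(f) for f in counts.features}
        if all(v is not None for v in known_lengths.values()):
            rpkm = compute_rpkm(counts, known_lengths)

    survivors: GenomeAnnotation | None = None
    de_called: pd.DataFrame | None = None

    for stage in selected:
        logger.info("stage %s: starting (outdir=%s)", stage, out)
        if stage == "discover":
            external = (
                read_predictor_calls(cfg.predictor_calls) if cfg.predictor_calls else ()
            )
            result = discover_lncrnas(
                candidates, ref, rpkm if rpkm is not None else counts,
                sequences=sequences, external_calls=external,
                min_len=cfg.min_len, min_max_expr=cfg.min_max_expr,
                min_samples=cfg.min_samples, min_exons=cfg.min_exons,
                background_mode=cfg.background_mode,
            )
            survivors = result.survivors
            write_gtf(survivors, out / "novel_lncrnas.gtf")
            write_bed6(survivors, out / "novel_lncrnas.bed")
            _write_fasta({t.id: sequences[t.id] for t in survivors}, out / "novel_lncrnas.fa")
            result.report.write(out / "filter_report.tsv")
            pd.Series(result.classes, name="lnc_class").rename_axis("feature_id").to_csv(
                out / "lncrna_classes.tsv", sep="\t"
            )
            logger.info("stage discover: %d novel lncRNAs (%s)",
                        len(survivors), dict(result.class_counts))
        elif stage == "de":
            res = nb_wald_test(counts, size_factors(counts))
            de_called = call_de(res, fc_up=cfg.fc_up, fc_down=cfg.fc_down, alpha=cfg.alpha)
            write_de_table(de_called, out / "de_results.tsv")
            logger.info("stage de: %s", de_summary(de_called))
        elif stage == "cis":
            if de_called is None:
                de_called = _read_de(out)
            if survivors is None:
                survivors = _read_survivors(cfg, out)
            de_lnc_ids = [
                t.id for t in survivors
                if t.id in de_called.index and de_called.loc[t.id, "direction"] != "ns"
            ]
            expr = rpkm if rpkm is not None else counts
            pairs = call_cis_targets(
                survivors.subset(de_lnc_ids), ref, expr,
                r_min=cfg.r_min, window_max=cfg.window_max, window_min=cfg.window_min,
                fold_changes=_gene_fold_changes(de_called, ref),
                sequences=sequences if cfg.use_homology else None,
                use_homology=cfg.use_homology, orientation=cfg.orientation,
            )
            cis_table(pairs).to_csv(out / "cis_targets.tsv", sep="\t", index=False)
            logger.info("stage cis: %d pairs", len(pairs))
        elif stage == "cerna":
            if survivors is None:
                survivors = _read_survivors(cfg, out)
            mirnas = read_fasta(cfg.mirna_fasta)
            lnc_seqs = {t.id: sequences[t.id] for t in survivors}
            mrna_ids = (
                [t.id for t in ref if t.biotype == ann_mod.KNOWN_MRNA] if ref else []
            )
            mrna_seqs = {i: sequences[i] for i in mrna_ids if i in sequences}
            lnc_sites = scan_targets(mirnas, lnc_seqs, cfg.site_types)
            mrna_sites = scan_targets(mirnas, mrna_seqs, cfg.site_types)
            net = build_cerna_network(lnc_sites, mrna_sites)
            write_site_table(lnc_sites + mrna_sites, out / "mirna_sites.tsv")
            export_network(net, out / "cerna_network.sif", "SIF")
            export_network(net, out / "cerna_network.graphml", "GraphML")
            logger.info("stage cerna: %d ceRNA edges", len(net.cerna_edges()))
        elif stage == "enrich":
            if de_called is None:
                de_called = _read_de(out)
            term_map = read_term_map(cfg.term_map)
            gene_fc = _gene_fold_changes(de_called, ref)
            universe = set()
            for members in term_map.values():
                universe |= members
            de_genes = {
                g for g in universe
                if g in de_called.index and de_called.loc[g, "direction"] != "ns"
            }
            # gene-level ids may differ from transcript ids: map via reference
            if ref is not None:
                tx_dir = {}
                for t in ref:
                    if t.id in de_called.index:
                        tx_dir[t.gene_id] = de_called.loc[t.id, "direction"]
                de_genes |= {g for g in universe if tx_dir.get(g, "ns") != "ns"}
            results = hypergeometric_enrichment(de_genes, universe, term_map,
                                                alpha=cfg.enrich_alpha)
            enrichment_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            logger.info("stage enrich: %d significant terms",
                        sum(r.significant for r in results))

    summary = summarize_outputs(cfg)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        for key, val in sorted(summary.items()):
            fh.write(f"{key}\t{val}\n")
    return summary


def _read_de(out: Path) -> pd.DataFrame:
    path = out / "de_results.tsv"
    if not path.exists():
        raise FileNotFoundError("cis/enrich stages need de_results.tsv (run the de stage)")
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_survivors(cfg: PipelineConfig, out: Path) -> GenomeAnnotation:
    path = out / "novel_lncrnas.gtf"
    if not path.exists():
        raise FileNotFoundError("downstream stages need novel_lncrnas.gtf (run discover)")
    return read_gtf(path, default_biotype=ann_mod.CANDIDATE)


def _gene_fold_changes(de_called: pd.DataFrame, ref: GenomeAnnotation | None) -> pd.Series:
    """Fold changes keyed by both transcript and gene id (genes take their
    first transcript's value)."""
    fc = de_called["fold_change"].copy()
    if ref is not None:
        extra = {}
        for t in ref:
            if t.id in fc.index and t.gene_id not in fc.index:
                extra.setdefault(t.gene_id, fc[t.id])
        if extra:
            fc = pd.concat([fc, pd.Series(extra)])
    return fc


def summarize_outputs(cfg: PipelineConfig) -> dict:
    """Recompute the report counts from whatever stage outputs exist on disk."""
    out = Path(cfg.outdir)
    summary: dict = {}
    classes = out / "lncrna_classes.tsv"
    if classes.exists():
        df = pd.read_csv(classes, sep="\t")
        summary["novel_lncrnas"] = int(len(df))
        for cls, n in df["lnc_class"].value_counts().items():
            summary[f"novel_lncrnas_{cls}"] = int(n)
    de_path = out / "de_results.tsv"
    if de_path.exists():
        df = pd.read_csv(de_path, sep="\t", index_col=0)
        summary["de_up"] = int((df["direction"] == "up").sum())
        summary["de_down"] = int((df["direction"] == "down").sum())
        summary["de_total"] = summary["de_up"] + summary["de_down"]
    cis_path = out / "cis_targets.tsv"
    if cis_path.exists():
        df = pd.read_csv(cis_path, sep="\t")
        summary["cis_pairs"] = int(len(df))
    sif = out / "cerna_network.sif"
    if sif.exists():
        n_cerna = sum(1 for line in open(sif) if "\tceRNA\t" in line)
        summary["cerna_edges"] = n_cerna
    enr = out / "enrichment.tsv"
    if enr.exists():
        df = pd.read_csv(enr, sep="\t")
        summary["enriched_terms"] = int(df["significant"].sum()) if len(df) else 0
    return summary
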