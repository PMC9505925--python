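"""End-to-end pipeline orchestration and summary reporting.

run_all() chains extraction -> intron features -> gene features -> pairing
(for the top-ranked intron) over one FASTA/GFF3 pair and writes every stage
artefact plus a merged summary.json.  All analysis stages are deterministic;
the only stochastic component of the package is the simulator, which is
seed-controlled separately.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import gene_features, genome_io, intron_features, pairing_model

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

SUMMARY_SECTIONS = (
    "lengths", "splice_sites", "branchpoints", "composition", "unique_introns",
    "lariat", "genes", "positional_bias", "pairing",
)


@dataclass
class RunConfig:
    fasta: str
    gff: str
    out_dir: str
    mode: str = "explicit-introns"       # GFF intron source: explicit rows or exon gaps
    flank: int = 6                       # exonic context width, nt
    bp_window: tuple[int, int] = intron_features.DEFAULT_BP_WINDOW
    bias_bins: int = 20                  # histogram bins for the positional ratio
    pairing_weights: dict | None = None  # PairType name -> weight; None = defaults
    top_n_unique: int = 10
    log_level: str = "INFO"
    rounding: str = "half-up"            # the only implemented percentage rounding


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@_stage("extract")
def _run_extract(config: RunConfig):
    genome = genome_io.parse_fasta(config.fasta)
    genes = genome_io.parse_gff(config.gff, mode=config.mode)
    introns = genome_io.extract_introns(genome, genes, flank=config.flank)
    genome_io.write_intron_outputs(introns, config.out_dir)
    return genome, genes, introns


@_stage("features")
def _run_features(config: RunConfig, introns) -> dict:
    out_dir = Path(config.out_dir)
    lengths = intron_features.classify_lengths(introns)
    terms = intron_features.terminal_dinucleotides(introns)
    calls = [intron_features.call_branchpoint(it, window=config.bp_window) for it in introns]
    bp_dist = intron_features.bp_position_distribution(calls, total=len(introns))
    comp = intron_features.composition(introns)
    unique = intron_features.tally_unique_introns(introns, denominator="class")

    pfm_frames = {}
    for length_class in lengths.counts:
        pfm = intron_features.build_pfm(introns, length_class, flank=config.flank)
        pfm_frames[length_class] = pfm
        frame = pfm.to_frame()
        frame.insert(0, "position", frame.index)
        frame.to_csv(out_dir / f"pfm_{length_class}nt.tsv", sep="\t", index=False,
                     lineterminator="\n", float_format="%.6f")

    with open(out_dir / "bp_calls.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tseq_id\tstart\tend\tstrand\tposition\tcanonical\n")
        for it, call in zip(introns, calls):
            pos = call.position if call.is_call else "NA"
            fh.write(f"{it.gene_id}\t{it.seq_id}\t{it.start}\t{it.end}\t{it.strand}"
                     f"\t{pos}\t{call.canonical}\n")

    top_seq, top_count, top_pct = unique[0]
    top_intron = next(it for it in introns if it.sequence == top_seq)
    top_call = intron_features.call_branchpoint(top_intron, window=config.bp_window)
    lariat = (
        intron_features.lariat_geometry(top_intron, top_call) if top_call.is_call else None
    )

    summary = {
        "lengths": {
            "total": lengths.total,
            "classes": {
                str(k): {"count": lengths.counts[k], "percent": lengths.shares[k]}
                for k in lengths.counts
            },
        },
        "splice_sites": {
            "gu_ag_fraction": terms.gu_ag_fraction,
            "n_used": terms.n_used,
            "n_excluded": terms.n_excluded,
            "pairs": {f"{a}..{b}": c for (a, b), c in sorted(terms.pairs.items())},
        },
        "branchpoints": {
            "total_introns": len(introns),
            "n_called": sum(1 for c in calls if c.is_call),
            "positions": {
                str(p): {"count": c, "percent": pct} for p, (c, pct) in bp_dist.items()
            },
        },
        "composition": {
            "au_pooled_percent": comp.au_pooled_percent,
            "au_mean_percent": comp.au_mean_percent,
            "n_used": comp.n_used,
            "n_excluded": comp.n_excluded,
        },
        "unique_introns": {
            "top": [
                {"sequence": s, "count": c, "percent": p}
                for s, c, p in unique[: config.top_n_unique]
            ],
            "n_unique": len(unique),
        },
        "lariat": (
            {
                "sequence": top_seq,
                "bp_position": top_call.position,
                "loop_length": lariat.loop_length,
                "tail_length": lariat.tail_length,
                "branch_nt": lariat.branch_nt,
            }
            if lariat
            else {"sequence": top_seq, "bp_position": None}
        ),
    }
    features_path = out_dir / "features.json"
    features_path.write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    return summary | {"_top_intron": top_intron, "_top_call": top_call, "_calls": calls}


@_stage("genes")
def _run_genes(config: RunConfig, genes) -> dict:
    out_dir = Path(config.out_dir)
    cohort = gene_features.summarize_genes(genes)
    introned = [g.gene_length for g in genes if g.n_introns > 0]
    intronless = [g.gene_length for g in genes if g.n_introns == 0]
    ttest = None
    if len(introned) >= 2 and len(intronless) >= 2:
        ttest = gene_features.student_t_test(introned, intronless, variant="pooled")
    bias = gene_features.positional_bias(genes, bins=config.bias_bins)
    bias.table.to_csv(out_dir / "bias.tsv", sep="\t", index=False,
                      lineterminator="\n", float_format="%.6f")
    summary = {
        "genes": {
            "n_genes": cohort.n_genes,
            "n_introned": cohort.n_introned,
            "n_intronless": cohort.n_intronless,
            "percent_introned": cohort.percent_introned,
            "introns_per_gene": {str(k): v for k, v in cohort.introns_per_gene.items()},
            "gene_length": (
                {
                    "t": ttest.t, "df": ttest.df, "p": ttest.p,
                    "mean_introned": ttest.mean_x, "mean_intronless": ttest.mean_y,
                    "median_introned": ttest.median_x, "median_intronless": ttest.median_y,
                }
                if ttest
                else None
            ),
        },
        "positional_bias": {
            "n_introns": int(len(bias.ratios)),
            "mean_ratio": bias.mean_ratio if len(bias.ratios) else None,
            "bin_edges": bias.bin_edges,
            "bin_counts": bias.bin_counts,
        },
    }
    (out_dir / "genes.json").write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    return summary


@_stage("pairing")
def _run_pairing(config: RunConfig, top_intron, top_call) -> dict:
    out_dir = Path(config.out_dir)
    weights = None
    if config.pairing_weights:
        weights = {
            pairing_model.PairType[name]: w for name, w in config.pairing_weights.items()
        }
    network = pairing_model.network_report(top_intron, top_call, weights=weights)
    text = network.render()
    (out_dir / "pairing.txt").write_text(text)
    payload = {
        "intron": network.intron_sequence,
        "bp_position": network.bp.position,
        "alignments": {
            name: {
                "motif": aln.motif.sequence,
                "offset": aln.offset,
                "score": aln.score,
                "bulge": aln.bulge,
                "region": aln.region,
                "region_origin": aln.region_origin,
                "pairs": [[rp, mp, t.value] for rp, mp, t in aln.pairs],
            }
            for name, aln in sorted(network.alignments.items())
        },
    }
    (out_dir / "pairing.json").write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
    return {"pairing": payload}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the merged summary."""
    logging.basicConfig(level=config.log_level)
    for path, label in ((config.fasta, "FASTA"), (config.gff, "GFF")):
        if not Path(path).exists():
            raise StageError(f"stage 'extract' failed: {label} input {path!r} not found")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    _genome, genes, introns = _run_extract(config)
    feat = _run_features(config, introns)
    top_intron, top_call = feat.pop("_top_intron"), feat.pop("_top_call")
    feat.pop("_calls")
    gene_summary = _run_genes(config, genes)
    pairing_summary = _run_pairing(config, top_intron, top_call)

    summary: dict = {"_meta": {"schema_version": SCHEMA_VERSION, "config": asdict(config)}}
    summary.update(feat)
    summary.update(gene_summary)
    summary.update(pairing_summary)
    (out_dir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2) + "\n")
    (out_dir / "summary.txt").write_text(render_summary(summary))
    return _jsonable(summary)


def render_summary(summary: dict) -> str:
    """Plain-text report over a run_all() summary, intron facts first."""
    L: list[str] = []
    lengths = summary["lengths"]
    L.append(f"Intron cohort: n={lengths['total']}")
    for cls, entry in lengths["classes"].items():
        L.append(f"  {cls} nt: {entry['percent']}% ({entry['count']}/{lengths['total']})")
    ss = summary["splice_sites"]
    L.append(f"GU...AG introns: {100 * ss['gu_ag_fraction']:.2f}% of {ss['n_used']}")
    bp = summary["branchpoints"]
    if bp["positions"]:
        L.append(f"Branchpoint adenosine positions (of {bp['total_introns']} introns):")
        for pos, entry in bp["positions"].items():
            L.append(f"  position {pos}: {entry['percent']}% ({entry['count']})")
    else:
        L.append("Branchpoint adenosine positions: n=0")
    comp = summary["composition"]
    L.append(f"AU content: {comp['au_pooled_percent']}% pooled, "
             f"{comp['au_mean_percent']}% per-intron mean")
    uniq = summary["unique_introns"]["top"]
    if uniq:
        top = uniq[0]
        L.append(f"Most abundant intron: {top['sequence']} "
                 f"({top['count']} occurrences, {top['percent']}%)")
    lar = summary["lariat"]
    if lar.get("bp_position"):
        L.append(f"Lariat geometry: {lar['loop_length']} nt loop, "
                 f"{lar['tail_length']} nt 3′ tail (branch at {lar['branch_nt']})")
    genes = summary["genes"]
    L.append(f"Genes: {genes['n_genes']} total, {genes['percent_introned']}% "
             f"intron-containing ({genes['n_introned']}/{genes['n_genes']})")
    if genes["introns_per_gene"]:
        hist = ", ".join(f"{k}:{v}" for k, v in genes["introns_per_gene"].items())
        L.append(f"Introns per gene: {hist}")
    else:
        L.append("Introns per gene: n=0")
    gl = genes.get("gene_length")
    if gl:
        L.append(f"Gene length medians: {gl['median_introned']:.0f} nt (introned) vs "
                 f"{gl['median_intronless']:.0f} nt (intronless); "
                 f"t={gl['t']:.4f}, df={gl['df']:.0f}, p={gl['p']:.3g}")
    pb = summary["positional_bias"]
    if pb["n_introns"]:
        L.append(f"Positional bias: mean 5′ ratio r = {pb['mean_ratio']:.4f} "
                 f"over {pb['n_introns']} introns")
    else:
        L.append("Positional bias: n=0")
    L.append("Pairing network computed for the top-ranked intron "
             f"({summary['pairing']['intron']}); see pairing.txt")
    return "\n".join(L) + "\n"
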