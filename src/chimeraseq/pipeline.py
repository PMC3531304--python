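"""End-to-end orchestration: discover -> verify -> EST support ->
junction quantification -> expression stats -> motif analysis.

Stages are plain functions over in-memory objects so they can be composed
in scripts and tests; :func:`run_all` wires them together on files, writes
one TSV per stage plus a Venn-style intersection summary (EST-supported /
read-validated / motif-bearing) and a run manifest with the resolved
configuration, and is deterministic given the seeds in the config.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .discovery import ChimeraCandidate, DiscoveryParams, discover_chimeras
from .est import est_support
from .formats_io import (
    GenomeStore,
    read_fasta,
    read_fastq,
    read_jaspar,
    read_psl,
    write_report,
)
from .junctions import (
    GenomeIndex,
    JunctionParams,
    build_junction_refs,
    call_junction_reads,
    map_genome,
    qc_trim,
    validate_events,
)
from .motifs import extract_region_pairs, find_shared_motif, match_pfm, tabulate_categories
from .simulate import default_pfm_library
from .splice import VerifiedCandidate, verify_candidates
from .stats import filter_unique_events, group_comparison

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "discovery": {"min_identity": 0.96, "min_align_len": 100, "max_junction_gap": 10,
                  "max_intron": 1_000_000},
    "verify": {"flank": 500, "min_intron": 30, "seed_len": 12},
    "est": {"min_identity": 0.96, "min_flank": 20, "min_ests": 3},
    "junction": {"min_overhang": 5, "max_mismatches": 2, "min_starts": 3,
                 "min_samples": 3, "qc_min_q": 20, "qc_mode": "mean"},
    "motifs": {"up_window": 2000, "down_window": 2000, "w_min": 10, "w_max": 30,
               "n_shuffles": 200, "p_max": 0.05, "pfm_p_threshold": 0.05},
}


def resolve_config(user: dict | None = None) -> dict:
    """Deep-merge a user config over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


# ---------------------------------------------------------------------------
# Stages


def stage_quantify(
    reads_by_sample: dict[str, list],
    read_lengths: dict[str, int],
    genome: GenomeStore,
    chimera_seqs: dict[str, str],
    junctions: dict[str, int],
    cfg: dict,
    genome_index: GenomeIndex | None = None,
) -> dict:
    """QC, genome pre-mapping, junction calling and validation for one
    cohort of samples sharing a trimmed read length."""
    jcfg = cfg["junction"]
    lengths = set(read_lengths[s] for s in reads_by_sample)
    if len(lengths) != 1:
        raise ValueError("stage_quantify expects one trimmed length per cohort")
    L = lengths.pop()
    params = JunctionParams(
        read_length=L,
        min_overhang=jcfg["min_overhang"],
        max_mismatches=jcfg["max_mismatches"],
        min_starts=jcfg["min_starts"],
        min_samples=jcfg["min_samples"],
    )
    index = genome_index or GenomeIndex(genome)
    refs = build_junction_refs(chimera_seqs, junctions, params)
    all_hits = []
    mapped_summary = {}
    for sample_id in sorted(reads_by_sample):
        cleaned = qc_trim(reads_by_sample[sample_id], L, jcfg["qc_min_q"], jcfg["qc_mode"])
        mapped = map_genome(cleaned, genome, params.max_mismatches, index=index)
        unmapped = [r for r in cleaned if mapped[r.read_id].status == "unmapped"]
        hits, shared = call_junction_reads(unmapped, refs, params)
        all_hits.extend(hits)
        mapped_summary[sample_id] = {
            "n_raw": len(reads_by_sample[sample_id]),
            "n_clean": len(cleaned),
            "n_unique": sum(m.status == "unique" for m in mapped.values()),
            "n_multi": sum(m.status == "multi" for m in mapped.values()),
            "n_unmapped": len(unmapped),
            "n_junction": sum(h.sample_id == sample_id for h in hits),
            "n_shared": len(shared),
        }
    event_ids = sorted(chimera_seqs)
    validation = validate_events(all_hits, params, event_ids=event_ids)
    counts = pd.DataFrame(
        0, index=event_ids, columns=sorted(reads_by_sample), dtype=int
    )
    for h in all_hits:
        counts.loc[h.event_id, h.sample_id] += 1
    return {"params": params, "hits": all_hits, "validation": validation,
            "counts": counts, "samples": mapped_summary}


def stage_motifs(
    candidates: list[ChimeraCandidate],
    genome: GenomeStore,
    pfms,
    cfg: dict,
):
    """Region-pair extraction, shared-motif search and PFM matching."""
    mcfg = cfg["motifs"]
    seed = cfg["seed"]
    shared = []
    matches_by_chimera: dict[str, list] = {}
    for cand in candidates:
        pairs = extract_region_pairs(
            cand, genome, up_window=mcfg["up_window"], down_window=mcfg["down_window"]
        )
        found = []
        for pair in pairs:
            m = find_shared_motif(
                pair.seq5, pair.seq3,
                w_min=mcfg["w_min"], w_max=mcfg["w_max"],
                n_shuffles=mcfg["n_shuffles"], seed=seed,
                p_max=mcfg["p_max"], chimera_id=cand.mrna_id,
            )
            if m is not None:
                m.category5, m.category3 = pair.category5, pair.category3
                found.append(m)
        if found:
            best = max(found, key=lambda m: m.score)
            shared.append(best)
            matches_by_chimera[cand.mrna_id] = match_pfm(
                best, pfms, n_shuffles=mcfg["n_shuffles"], seed=seed,
                p_threshold=mcfg["pfm_p_threshold"],
            )
    matched_ids = {cid for cid, ms in matches_by_chimera.items() if ms}
    total, matched = tabulate_categories(shared, matched_ids)
    return shared, matches_by_chimera, total, matched


# ---------------------------------------------------------------------------
# File-level driver


def _candidate_row(c: ChimeraCandidate) -> dict:
    return {
        "mrna_id": c.mrna_id, "fusion_class": c.fusion_class, "order_type": c.order_type,
        "gap_overlap": c.gap_overlap, "junction_q": c.junction_q,
        "chrom5": c.partner5.chrom, "strand5": c.partner5.strand,
        "start5": c.partner5.start, "end5": c.partner5.end,
        "chrom3": c.partner3.chrom, "strand3": c.partner3.strand,
        "start3": c.partner3.start, "end3": c.partner3.end,
    }


def _verified_row(v: VerifiedCandidate) -> dict:
    return {
        "mrna_id": v.candidate.mrna_id, "status": v.check.status,
        "aligned_precisely": v.check.aligned_precisely,
        "donor": v.check.donor, "acceptor": v.check.acceptor,
        "canonical": v.check.canonical, "frame_ok": v.check.frame_ok,
        "passed": v.passed, "reason": v.reason or "",
    }


def run_all(
    genome_fasta: str | Path,
    mrna_fasta: str | Path,
    psl_path: str | Path,
    est_fasta: str | Path,
    read_manifest: list[dict],
    outdir: str | Path,
    config: dict | None = None,
    pfm_path: str | Path | None = None,
) -> dict:
    """Run every stage on files and write one report per stage.

    ``read_manifest`` rows carry sample_id, fastq path, group (sex or
    breed), cohort name and trimmed read length.  Returns a summary dict
    (also written as ``manifest.json``); any stage failure raises with the
    stage name, leaving earlier outputs in place.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(genome_fasta)
    mrnas = read_fasta(mrna_fasta)
    records = read_psl(psl_path)
    ests = read_fasta(est_fasta)
    pfms = read_jaspar(pfm_path) if pfm_path else default_pfm_library()

    # discover
    dcfg = cfg["discovery"]
    candidates, rejects = discover_chimeras(records, DiscoveryParams(**dcfg))
    write_report([_candidate_row(c) for c in candidates], outdir / "candidates.tsv", "candidates")

    # verify
    vcfg = cfg["verify"]
    verified = verify_candidates(candidates, genome, mrnas, **vcfg)
    write_report([_verified_row(v) for v in verified], outdir / "verified.tsv", "verified")
    passed = [v.candidate for v in verified if v.passed]
    rejects += [
        {"mrna_id": v.candidate.mrna_id, "stage": "verify", "reason": v.reason}
        for v in verified if not v.passed
    ]
    passed_ids = {c.mrna_id for c in passed}
    chim_seqs = {cid: mrnas[cid] for cid in passed_ids}
    junctions = {c.mrna_id: c.junction_q for c in passed}

    # EST support
    ecfg = cfg["est"]
    support, _ = est_support(chim_seqs, junctions, dict(ests.sequences),
                             min_identity=ecfg["min_identity"],
                             min_flank=ecfg["min_flank"], min_ests=ecfg["min_ests"])
    write_report(
        [{"chimera_id": cid, "n_spanning": s.n_spanning, "supported": s.supported,
          "est_ids": ",".join(s.spanning_est_ids)} for cid, s in support.items()],
        outdir / "est_support.tsv", "est_support",
    )
    rejects += [{"mrna_id": cid, "stage": "est", "reason": "est"}
                for cid, s in support.items() if not s.supported]

    # quantification per cohort
    index = GenomeIndex(genome)
    cohorts: dict[str, list[dict]] = {}
    for row in read_manifest:
        cohorts.setdefault(row["cohort"], []).append(row)
    quant = {}
    validated_ids: set[str] = set()
    for cohort in sorted(cohorts):
        rows = cohorts[cohort]
        reads_by_sample = {r["sample_id"]: read_fastq(r["fastq"], r["sample_id"]) for r in rows}
        lengths = {r["sample_id"]: r["trimmed_length"] for r in rows}
        quant[cohort] = stage_quantify(reads_by_sample, lengths, genome, chim_seqs,
                                       junctions, cfg, genome_index=index)
        validated_ids |= {e for e, v in quant[cohort]["validation"].items() if v.validated}
    first = quant[sorted(quant)[0]] if quant else None
    if quant:
        count_rows = []
        val_rows = []
        for cohort, q in quant.items():
            for event_id, row in q["counts"].iterrows():
                for sample_id, n in row.items():
                    count_rows.append({"event_id": event_id, "sample_id": sample_id, "n_reads": int(n)})
            for event_id, v in q["validation"].items():
                val_rows.append({"event_id": event_id, "n_reads": v.n_reads,
                                 "n_start_positions": v.n_start_positions,
                                 "n_samples": v.n_samples, "validated": v.validated})
        write_report(count_rows, outdir / "junction_counts.tsv", "junction_counts")
        write_report(val_rows, outdir / "validation.tsv", "validation")
    rejects += [{"mrna_id": cid, "stage": "quantify", "reason": "starts"}
                for cid in sorted(passed_ids - validated_ids)]
    write_report(rejects, outdir / "rejects.tsv", "rejects")

    # expression statistics on the primary (first) cohort
    stats_df = pd.DataFrame()
    if first is not None:
        groups = {r["sample_id"]: r["group"] for r in cohorts[sorted(cohorts)[0]]}
        matrix = first["counts"]
        unique = filter_unique_events(
            sorted(validated_ids), passed, matrix
        )
        if unique and len(set(groups.values())) == 2:
            stats_df = group_comparison(matrix.loc[unique], groups)
        stats_df.to_csv(outdir / "stats.tsv", sep="\t", index=False)

    # motifs
    shared, matches, total, matched = stage_motifs(passed, genome, pfms, cfg)
    motif_rows = []
    for m in shared:
        ms = matches.get(m.chimera_id, [])
        best = ms[0] if ms else None
        motif_rows.append({
            "chimera_id": m.chimera_id, "category5": m.category5, "category3": m.category3,
            "width": m.width, "site5": m.site5, "site3": m.site3, "score": m.score,
            "empirical_p": m.empirical_p,
            "best_pfm": best.pfm_id if best else "", "best_pfm_p": best.p if best else "",
            "best_pfm_q": best.q if best else "",
        })
    write_report(motif_rows, outdir / "motifs.tsv", "motifs")
    table1 = pd.DataFrame(total, index=[f"5p_{c}" for c in ("up", "exon", "intron", "down")],
                          columns=[f"3p_{c}" for c in ("up", "exon", "intron", "down")])
    table1.to_csv(outdir / "table1.tsv", sep="\t")

    # Venn-style intersections
    est_ids = {cid for cid, s in support.items() if s.supported}
    motif_ids = {m.chimera_id for m in shared}
    venn = {
        "passed_verify": len(passed_ids),
        "est_supported": len(est_ids),
        "read_validated": len(validated_ids),
        "motif_bearing": len(motif_ids),
        "est_and_reads": len(est_ids & validated_ids),
        "est_and_motif": len(est_ids & motif_ids),
        "reads_and_motif": len(validated_ids & motif_ids),
        "all_three": len(est_ids & validated_ids & motif_ids),
    }
    write_report([{"group": k, "count": v} for k, v in venn.items()], outdir / "venn.tsv", "venn")

    manifest = {"version": __version__, "config": cfg, "venn": venn,
                "n_candidates": len(candidates), "n_passed_verify": len(passed_ids)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
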