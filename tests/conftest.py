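"""Shared fixtures: one synthetic study (and its full pipeline products)
reused across the suite, plus a 1%-error variant for error-model checks."""

from __future__ import annotations

import pytest
from hypothesis import settings

from chimeraseq.discovery import discover_chimeras
from chimeraseq.est import est_support
from chimeraseq.junctions import GenomeIndex
from chimeraseq.pipeline import resolve_config, stage_quantify
from chimeraseq.simulate import simulate_study
from chimeraseq.splice import verify_candidates

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

STUDY_SEED = 1


def _run_pipeline(study):
    """Discover -> verify -> EST -> quantify, with a reject-reason log."""
    chim = study.chimeras
    candidates, rejects = discover_chimeras(chim.psl_records)
    verified = verify_candidates(candidates, study.genome, chim.chimera_seqs)
    passed = [v.candidate for v in verified if v.passed]
    seqs = {c.mrna_id: chim.chimera_seqs[c.mrna_id] for c in passed}
    junctions = {c.mrna_id: c.junction_q for c in passed}
    support, est_hits = est_support(seqs, junctions, study.ests)

    cfg = resolve_config()
    index = GenomeIndex(study.genome)
    quant = {}
    for cohort in ("liver", "muscle"):
        reads = {s.sample_id: study.reads[s.sample_id]
                 for s in study.samples if s.cohort == cohort}
        lengths = {s.sample_id: s.trimmed_length
                   for s in study.samples if s.cohort == cohort}
        quant[cohort] = stage_quantify(reads, lengths, study.genome, seqs,
                                       junctions, cfg, genome_index=index)

    reasons: dict[str, str] = {r["mrna_id"]: r["reason"] for r in rejects}
    for v in verified:
        if not v.passed:
            reasons[v.candidate.mrna_id] = v.reason
    for cid, s in support.items():
        if not s.supported:
            reasons.setdefault(cid, "est")
    validated = {e for q in quant.values()
                 for e, v in q["validation"].items() if v.validated}
    for cid in seqs:
        if cid not in validated:
            reasons.setdefault(cid, "starts")
    survivors = {cid for cid in seqs
                 if support[cid].supported and cid in validated}
    return {
        "study": study,
        "candidates": candidates,
        "rejects": rejects,
        "verified": verified,
        "passed": passed,
        "support": support,
        "est_hits": est_hits,
        "quant": quant,
        "reasons": reasons,
        "survivors": survivors,
    }


@pytest.fixture(scope="session")
def study0():
    return simulate_study(seed=STUDY_SEED, error_rate=0.0)


@pytest.fixture(scope="session")
def pipeline0(study0):
    return _run_pipeline(study0)


@pytest.fixture(scope="session")
def pipeline_err():
    return _run_pipeline(simulate_study(seed=STUDY_SEED, error_rate=0.01))
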