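"""End-to-end analysis pipeline: parse -> classify -> build -> measure."""

from __future__ import annotations

from dataclasses import asdict
from typing import Iterable

from . import build, classify, geometry
from .sequence import (ClipSequence, amphipathicity_profile, lm_tag,
                       parse_clip_file)

__all__ = ["analyze_sequence", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def analyze_sequence(seq: ClipSequence, build_model: bool = True) -> dict:
    """Full report for one CLiP: tag, motif assignment, and (optionally) a
    de novo model with its geometry measurements."""
    l, m = lm_tag(seq)  # noqa: E741
    assign = classify.classify_motif(l, m)
    report: dict = {
        "name": seq.name,
        "tag": f"{l}:{m}",
        "l": l,
        "m": m,
        "latch_pos": seq.latch_pos,
        "latch_residue": seq.residue(seq.latch_pos).code,
        "motif": assign.motif,
        "helix_span": assign.helix_span,
        "loop_span": assign.loop_span,
        "loop_count": assign.loop_count,
        "amphipathicity": list(amphipathicity_profile(seq)),
    }
    if not build_model or assign.helix_span is None:
        return report
    try:
        model = build.build_clip_model(seq)
    except build.ClosureError as err:
        raise PipelineError("build", str(err)) from err
    hand = geometry.handedness(model)
    report["handedness"] = "".join(
        {"alphaL": "L", "alphaR": "R", "other": "-"}[hand[i]]
        for i in range(1, l + 1))
    report["motif_from_geometry"] = geometry.detect_motif(model, seq)
    report["hbonds"] = [
        {"donor": hb.donor, "acceptor": hb.acceptor,
         "separation": hb.separation, "distance": round(hb.distance, 2)}
        for hb in geometry.detect_hbonds(model)]
    report["closure_gap"] = round(
        build.closure_gap(model, seq.latch_pos), 3)
    helix_span = assign.helix_span
    ring_span = (seq.latch_pos, l)
    if helix_span[1] - helix_span[0] + 1 >= 5:
        fit = geometry.macrocycle_bend(model, ring_span, helix_span)
        report["bend_angle"] = round(fit.bend_angle, 1)
        score, faces = geometry.amphipathic_segregation(seq, model,
                                                        helix_span)
        report["segregation_score"] = round(score, 3)
        report["faces"] = faces
    report["_model"] = model
    return report


def run_pipeline(lines: Iterable[str], build_models: bool = True
                 ) -> list[dict]:
    """Analyze every CLiP notation line; returns one report per sequence."""
    try:
        seqs = parse_clip_file(lines)
    except Exception as err:
        raise PipelineError("parse", str(err)) from err
    if not seqs:
        raise PipelineError("parse", "no sequences found in input")
    return [analyze_sequence(s, build_model=build_models) for s in seqs]
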