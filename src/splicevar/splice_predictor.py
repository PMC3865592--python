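"""Splice-site loss prediction by consensus of three scoring models.

Three transparent, independently parameterized models score a candidate
donor/acceptor window against a uniform background:

* ``wmm``  — position weight matrix (0th-order): per-position base
  probabilities with pseudocount; score is the summed log2 odds.
* ``wam``  — weight array model (1st-order Markov): a marginal for the first
  position plus per-adjacent-position conditional probabilities, capturing
  dinucleotide dependence at the splice signal.
* ``consensus_ic`` — information-content-weighted consensus match: each
  position contributes its IC when the query matches the modal training base;
  a mismatch at a position of IC close to 2 bits (a near-invariant core
  position such as the GT/AG dinucleotide) multiplicatively disqualifies the
  site via a ``(1 - IC/2)`` penalty.

Log-odds scores are floored at the background (raw 0) and divided by the
model's attainable maximum, giving a [0, 1] scale on which sequences no
better than random score 0 and the training-optimal sequence scores 1. A
site is *recognized* when the normalized score reaches the recognition
threshold (default 0.4). A variant is called a splice-site loss only when
all three methods recognize the wild-type window and none recognizes the
mutant window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import (
    COMPLEMENT,
    GenomeSequence,
    SpliceBoundary,
    Transcript,
    WindowGeometry,
    boundary_window,
    window_positions,
)
from .splice_annotator import SpliceAnnotation

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BACKGROUND = 0.25
METHODS = ("wmm", "wam", "consensus_ic")


class PredictionError(ValueError):
    pass


@dataclass(frozen=True)
class PredictorParams:
    recognition_threshold: float = 0.4
    consensus_rule: str = "all-of-3"
    probability_threshold: float = 0.9

    def __post_init__(self) -> None:
        for name in ("recognition_threshold", "probability_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise PredictionError(f"{name} must be in [0, 1]")


@dataclass
class SpliceModel:
    kind: str  # donor | acceptor
    method: str  # wmm | wam | consensus_ic
    length: int
    pseudocount: float
    # wmm/consensus_ic: probs (L, 4); wam additionally cond (L-1, 4, 4)
    probs: np.ndarray = field(repr=False)
    cond: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise PredictionError(f"unknown method {self.method!r}")
        if self.probs.shape != (self.length, 4):
            raise PredictionError("probability matrix shape mismatch")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise PredictionError("probability rows must sum to 1")
        if self.method == "wam":
            if self.cond is None or self.cond.shape != (self.length - 1, 4, 4):
                raise PredictionError("wam model requires conditional matrices")
            if not np.allclose(self.cond.sum(axis=2), 1.0, atol=1e-9):
                raise PredictionError("conditional probability rows must sum to 1")

    # -- raw log-odds and its attainable maximum ------------------------

    def _raw_wmm(self, seq: str) -> float:
        raw = 0.0
        for i, b in enumerate(seq):
            if b in BASE_INDEX:
                raw += math.log2(self.probs[i, BASE_INDEX[b]] / BACKGROUND)
        return raw

    def _max_wmm(self) -> float:
        return float(np.log2(self.probs.max(axis=1) / BACKGROUND).sum())

    def _raw_wam(self, seq: str) -> float:
        raw = 0.0
        prev: int | None = None
        for i, b in enumerate(seq):
            bi = BASE_INDEX.get(b)
            if bi is None:  # N: background contribution, breaks the chain
                prev = None
                continue
            if i == 0 or prev is None:
                raw += math.log2(self.probs[i, bi] / BACKGROUND)
            else:
                raw += math.log2(self.cond[i - 1, prev, bi] / BACKGROUND)
            prev = bi
        return raw

    def _max_wam(self) -> float:
        best = np.log2(self.probs[0] / BACKGROUND)
        for i in range(1, self.length):
            step = np.log2(self.cond[i - 1] / BACKGROUND)  # (prev, cur)
            best = (best[:, None] + step).max(axis=0)
        return float(best.max())

    def _ic_weights(self) -> tuple[np.ndarray, np.ndarray]:
        entropy = -(self.probs * np.log2(self.probs)).sum(axis=1)
        ic = np.clip(2.0 - entropy, 0.0, 2.0)
        modal = self.probs.argmax(axis=1)  # argmax ties -> lowest index = lexicographic
        return ic, modal

    def score(self, sequence: str) -> float:
        """Normalized [0, 1] site score; N bases score as background."""
        sequence = sequence.upper()
        if len(sequence) != self.length:
            raise PredictionError(
                f"{self.method}/{self.kind}: window length {len(sequence)} != "
                f"model length {self.length}"
            )
        bad = set(sequence) - set("ACGTN")
        if bad:
            raise PredictionError(f"non-ACGTN characters in window: {sorted(bad)}")
        if self.method == "wmm":
            raw, max_raw = self._raw_wmm(sequence), self._max_wmm()
        elif self.method == "wam":
            raw, max_raw = self._raw_wam(sequence), self._max_wam()
        else:
            ic, modal = self._ic_weights()
            total = float(ic.sum())
            if total <= 0.0:
                return 0.5
            matched = 0.0
            penalty = 1.0
            for i, b in enumerate(sequence):
                bi = BASE_INDEX.get(b)
                if bi is None:
                    continue
                if bi == modal[i]:
                    matched += ic[i]
                else:
                    penalty *= max(0.0, 1.0 - ic[i] / 2.0)
            return float(np.clip(matched / total * penalty, 0.0, 1.0))
        if max_raw <= 0.0:
            return 0.0
        return float(np.clip(raw, 0.0, max_raw) / max_raw)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "method": self.method,
            "length": self.length,
            "pseudocount": self.pseudocount,
            "probs": self.probs.tolist(),
        }
        if self.cond is not None:
            d["cond"] = self.cond.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpliceModel":
        cond = np.asarray(d["cond"], dtype=float) if "cond" in d else None
        return cls(
            d["kind"], d["method"], d["length"], d["pseudocount"],
            np.asarray(d["probs"], dtype=float), cond,
        )


def train(
    sequences: Sequence[str],
    kind: str,
    method: str,
    pseudocount: float = 0.1,
) -> SpliceModel:
    """Estimate a splice-site model from aligned equal-length site sequences."""
    if len(sequences) < 2:
        raise PredictionError("training requires at least 2 sequences")
    seqs = [s.upper() for s in sequences]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise PredictionError("ragged training sequences (all must be equal length)")
    for s in seqs:
        if set(s) - set("ACGT"):
            raise PredictionError(f"training sequence with non-ACGT base: {s}")
    counts = np.zeros((length, 4))
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, BASE_INDEX[b]] += 1
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    cond = None
    if method == "wam":
        pair = np.zeros((length - 1, 4, 4))
        for s in seqs:
            for i in range(1, length):
                pair[i - 1, BASE_INDEX[s[i - 1]], BASE_INDEX[s[i]]] += 1
        cond = (pair + pseudocount) / (pair.sum(axis=2, keepdims=True) + 4 * pseudocount)
    return SpliceModel(kind, method, length, pseudocount, probs, cond)


def score_window(model: SpliceModel, window_sequence: str) -> float:
    """Functional alias for :meth:`SpliceModel.score`."""
    return model.score(window_sequence)


# -- bundled training data -----------------------------------------------
#
# Authored canonical-site training windows with near-invariant cores
# (donor GT at +1/+2 and G at +5; acceptor AG at -2/-1) and deliberately
# weak flanks, so that single-base core substitutions fall below the
# recognition threshold while intact sites stay well above it.

_DONOR_COLUMNS = [
    "CCCCCCCCAAAAAGGGGTTT",  # -3
    "AAAAAAAAACCCCCGGGTTT",  # -2
    "GGGGGGGGGAAAAACCCTTT",  # -1
    "GGGGGGGGGGGGGGGGGGGG",  # +1 (invariant)
    "TTTTTTTTTTTTTTTTTTTT",  # +2 (invariant)
    "AAAAAAAAGGGGGGCCCTTT",  # +3
    "AAAAAAAAGGGGGGCCCTTT",  # +4
    "GGGGGGGGGGGGGGGGGGGG",  # +5 (invariant)
    "TTTTTTTTAAAAAACCCGGG",  # +6
]

_ACCEPTOR_TRACT_COLUMN = "CCCCCCTTTTTTAAAAGGGG"  # each of -20..-3
_ACCEPTOR_COLUMNS = (
    [_ACCEPTOR_TRACT_COLUMN] * 18
    + [
        "AAAAAAAAAAAAAAAAAAAA",  # -2 (invariant)
        "GGGGGGGGGGGGGGGGGGGG",  # -1 (invariant)
        "GGGGGGGGGAAAAACCCTTT",  # +1 exonic
        "TTTTTTCCCCCCAAAAGGGG",  # +2 exonic
        "CCCCCCTTTTTTAAAAGGGG",  # +3 exonic
    ]
)


def _columns_to_sequences(columns: list[str]) -> list[str]:
    """Transpose per-position base columns into aligned training sequences.

    Each column is shuffled with a fixed seed so adjacent positions pair
    near-independently (the first-order model then reflects the marginals
    rather than artifacts of column ordering)."""
    import random

    rng = random.Random(7)
    n = len(columns[0])
    shuffled = []
    for col in columns:
        chars = list(col)
        rng.shuffle(chars)
        shuffled.append(chars)
    return ["".join(col[j] for col in shuffled) for j in range(n)]


def bundled_training_sequences(kind: str) -> list[str]:
    if kind == "donor":
        return _columns_to_sequences(_DONOR_COLUMNS)
    if kind == "acceptor":
        return _columns_to_sequences(_ACCEPTOR_COLUMNS)
    raise PredictionError(f"unknown site kind {kind!r}")


def default_models(
    geometry: WindowGeometry = WindowGeometry(), pseudocount: float = 0.1
) -> dict[str, dict[str, SpliceModel]]:
    """Train the bundled models: {kind: {method: SpliceModel}}."""
    out: dict[str, dict[str, SpliceModel]] = {}
    for kind in ("donor", "acceptor"):
        seqs = bundled_training_sequences(kind)
        if len(seqs[0]) != geometry.length(kind):
            raise PredictionError(
                f"bundled {kind} training length {len(seqs[0])} does not match "
                f"geometry {geometry.length(kind)}"
            )
        out[kind] = {m: train(seqs, kind, m, pseudocount) for m in METHODS}
    return out


def save_models(models: dict[str, dict[str, SpliceModel]], path: str | Path) -> None:
    payload = {k: {m: mod.to_dict() for m, mod in d.items()} for k, d in models.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict[str, dict[str, SpliceModel]]:
    payload = json.loads(Path(path).read_text())
    return {
        k: {m: SpliceModel.from_dict(d) for m, d in methods.items()}
        for k, methods in payload.items()
    }


# -- prediction ----------------------------------------------------------


@dataclass(frozen=True)
class MethodScores:
    wt_score: float
    mut_score: float
    wt_recognized: bool
    mut_recognized: bool


@dataclass(frozen=True)
class SplicePrediction:
    annotation: SpliceAnnotation | None
    kind: str
    per_method: dict[str, MethodScores]
    effect: str  # donor_lost | acceptor_lost | none
    consensus: bool
    probability: float


def predict(
    wt_window: str,
    mut_window: str,
    models_by_method: Mapping[str, SpliceModel],
    params: PredictorParams = PredictorParams(),
    annotation: SpliceAnnotation | None = None,
) -> SplicePrediction:
    """Score the wild-type and mutant windows and form the 3-way consensus call."""
    wt_window, mut_window = wt_window.upper(), mut_window.upper()
    if wt_window == mut_window:
        raise PredictionError("wild-type and mutant windows are identical")
    kinds = {m.kind for m in models_by_method.values()}
    if len(kinds) != 1:
        raise PredictionError("models of mixed site kinds passed to predict")
    kind = kinds.pop()

    per_method: dict[str, MethodScores] = {}
    ratio_product = 1.0
    consensus = True
    for method, model in sorted(models_by_method.items()):
        wt = model.score(wt_window)
        mut = model.score(mut_window)
        rec_wt = wt >= params.recognition_threshold
        rec_mut = mut >= params.recognition_threshold
        per_method[method] = MethodScores(wt, mut, rec_wt, rec_mut)
        consensus = consensus and rec_wt and not rec_mut
        ratio_product *= min(1.0, mut / wt) if wt > 0 else 1.0
    effect = f"{kind}_lost" if consensus else "none"
    probability = min(1.0, max(0.0, 1.0 - ratio_product))
    return SplicePrediction(annotation, kind, per_method, effect, consensus, probability)


def _boundary_for(annotation: SpliceAnnotation, transcript: Transcript) -> SpliceBoundary:
    for b in transcript.boundaries():
        if b.kind == annotation.side and b.exon_index == annotation.exon_index:
            return b
    raise PredictionError(
        f"no {annotation.side} boundary at exon {annotation.exon_index} "
        f"of {transcript.transcript_id}"
    )


def mutant_window(
    wt_window: str,
    boundary: SpliceBoundary,
    annotation: SpliceAnnotation,
    geometry: WindowGeometry,
) -> str | None:
    """Substitute the variant base into the window; None if outside the footprint."""
    positions = window_positions(boundary, geometry)
    v = annotation.variant
    if v.position not in positions:
        return None
    idx = positions.index(v.position)
    alt = v.alt_base
    if boundary.strand == "-":
        alt = alt.translate(COMPLEMENT)
    return wt_window[:idx] + alt + wt_window[idx + 1 :]


def batch_predict(
    annotations: Iterable[SpliceAnnotation],
    genome: GenomeSequence,
    transcripts: Sequence[Transcript],
    models: dict[str, dict[str, SpliceModel]] | None = None,
    params: PredictorParams = PredictorParams(),
    geometry: WindowGeometry = WindowGeometry(),
) -> list[SplicePrediction]:
    """Predict every splicing annotation with the models matching its side."""
    if models is None:
        models = default_models(geometry)
    by_id = {t.transcript_id: t for t in transcripts}
    predictions = []
    for ann in annotations:
        if ann.region != "splicing":
            continue
        transcript = by_id[ann.transcript_id]
        boundary = _boundary_for(ann, transcript)
        wt = boundary_window(genome, boundary, geometry)
        mut = mutant_window(wt, boundary, ann, geometry)
        if mut is None:
            # variant outside the scoring footprint: site intact by construction
            scores = {
                m: MethodScores(s := model.score(wt), s,
                                s >= params.recognition_threshold,
                                s >= params.recognition_threshold)
                for m, model in sorted(models[ann.side].items())
            }
            predictions.append(
                SplicePrediction(ann, ann.side, scores, "none", False, 0.0)
            )
            continue
        predictions.append(predict(wt, mut, models[ann.side], params, annotation=ann))
    return predictions


def predictions_to_tsv(predictions: Iterable[SplicePrediction]) -> str:
    """Report with per-method wt/mut scores; '-' marks an unrecognized site."""
    lines = ["locus\thgvs_c\tside\t" + "\t".join(f"{m}_wt\t{m}_mut" for m in METHODS)
             + "\teffect\tconsensus\tprobability"]
    for p in predictions:
        ann = p.annotation
        v_locus = ann.variant.locus if ann else "."
        hgvs = (ann.hgvs_c or ".") if ann else "."
        cells = [v_locus, hgvs, p.kind]
        for m in METHODS:
            s = p.per_method[m]
            cells.append(f"{s.wt_score:.3f}" if s.wt_recognized else "-")
            cells.append(f"{s.mut_score:.3f}" if s.mut_recognized else "-")
        cells += [p.effect, str(int(p.consensus)), f"{p.probability:.3f}"]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
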