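"""Scoring pipeline output against simulator ground truth.

Recovery is a join on the unordered gene pair: a planted event is *detected*
when its (donor, derived) pair appears in some pipeline event (directly or
as a member of a linked set).  Geography compares location and orientation;
class compares the reporting category (complete/partial/chimeric/retro);
Ks error is |estimated - realized| where realized is the NG86 value the
simulator measured on the planted copies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duplication_structure import DuplicationEvent
from .synthetic_genome import TruthRecord


@dataclass(frozen=True)
class RecoveryScore:
    n_truth: int
    n_detected: int
    n_geography_correct: int
    n_class_correct: int
    n_class_scored: int
    ks_errors: tuple[float, ...]

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_truth if self.n_truth else 1.0

    @property
    def geography_accuracy(self) -> float:
        return self.n_geography_correct / self.n_detected if self.n_detected else 0.0

    @property
    def class_accuracy(self) -> float:
        return self.n_class_correct / self.n_class_scored if self.n_class_scored else 0.0

    @property
    def ks_mae(self) -> float:
        return float(np.mean(self.ks_errors)) if self.ks_errors else float("nan")


def score_recovery(events: list[DuplicationEvent],
                   truth: list[TruthRecord]) -> RecoveryScore:
    by_pair: dict[frozenset[str], DuplicationEvent] = {}
    for ev in events:
        for g1, g2 in (ev.members or ((ev.gene1, ev.gene2),)):
            by_pair[frozenset((g1, g2))] = ev

    detected = geo_ok = cls_ok = cls_n = 0
    ks_errors: list[float] = []
    for t in truth:
        ev = by_pair.get(t.pair)
        if ev is None:
            continue
        detected += 1
        loc_ok = ev.location == t.location
        orient_ok = (ev.orientation == t.orientation
                     if t.location == "intrachromosomal"
                     else ev.orientation in ("n/a", None))
        if loc_ok and orient_ok:
            geo_ok += 1
        cls_n += 1
        if ev.category == t.event_class:
            cls_ok += 1
        if ev.ks is not None and not ev.linked:
            ks_errors.append(abs(ev.ks - t.realized_ks))
    return RecoveryScore(n_truth=len(truth), n_detected=detected,
                         n_geography_correct=geo_ok, n_class_correct=cls_ok,
                         n_class_scored=cls_n, ks_errors=tuple(ks_errors))
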