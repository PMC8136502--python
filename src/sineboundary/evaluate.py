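"""Recovery metrics of pipeline output against simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .polymorphism import InsertionCall
from .synthetic import GroundTruth


@dataclass
class ScanRecovery:
    n_truth: int
    n_calls: int
    n_matched: int  # calls matching a planted event (breakpoint within tol)
    n_truth_recovered: int
    breakpoint_tol: int

    @property
    def sensitivity(self) -> float:
        return self.n_truth_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_calls if self.n_calls else float("nan")


def match_scan_calls(
    calls: list[InsertionCall],
    truth: GroundTruth,
    tol: int = 5,
    strain_names: tuple[str, str] = ("A", "B"),
) -> ScanRecovery:
    """Match insertion calls to planted strain-specific events by carrier
    strain and leftmost breakpoint (within ``tol`` bases). Control events
    (below the length floor / below occupancy) are not counted as truth."""
    events = truth.specific_insertions(kinds=("regular",))
    recovered = set()
    n_matched = 0
    for call in calls:
        hit = None
        for idx, e in enumerate(events):
            name = strain_names[0] if e.strain == "A" else strain_names[1]
            start = e.start_A if e.strain == "A" else e.start_B
            if call.carrier == name and abs(call.candidate.start - start) <= tol:
                hit = idx
                break
        if hit is not None:
            n_matched += 1
            recovered.add(hit)
    return ScanRecovery(
        n_truth=len(events),
        n_calls=len(calls),
        n_matched=n_matched,
        n_truth_recovered=len(recovered),
        breakpoint_tol=tol,
    )


def subfamily_accuracy(calls: list[InsertionCall], truth: GroundTruth,
                       tol: int = 5) -> float:
    """Fraction of matched calls labelled with the planted subfamily."""
    events = truth.specific_insertions(kinds=("regular",))
    ok = n = 0
    for call in calls:
        for e in events:
            start = e.start_A if e.strain == "A" else e.start_B
            name = "A" if e.strain == "A" else "B"
            if call.carrier == name and abs(call.candidate.start - start) <= 5:
                n += 1
                ok += call.subfamily == e.subfamily
                break
    return ok / n if n else float("nan")
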