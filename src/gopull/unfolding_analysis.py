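"""Trajectory-level unfolding analyses.

Helicity fraction versus extension, per-helix-pair native-contact fractions
Q, attached-helix state classification (five-helix → three-helix →
zero-helix style labels), and unfolding-event detection on PMF or force
profiles.

A native inter-helix contact counts as "formed" in a frame when its current
distance is below 1.5× the native distance (configurable); a helix is
"attached" while its best pairwise Q against any other helix is at or above
the attachment threshold (default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .go_model import ContactMap
from .structure_io import HelixAnnotation, HelixDetectorParams, assign_helices

__all__ = [
    "HelicityTrace",
    "StateCall",
    "IntermediateCall",
    "helicity_trace",
    "helix_pair_contact_fraction",
    "classify_state",
    "replica_state_sequence",
    "unfolding_events_from_pmf",
    "pulling_state_census",
]

FORMED_FACTOR = 1.5  # r < factor × native distance ⇒ contact formed
ATTACH_THRESHOLD = 0.5


@dataclass
class HelicityTrace:
    extension: np.ndarray  # Å per frame
    n_helical: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.extension) == len(self.n_helical) == len(self.fraction)):
            raise ValueError("trace arrays must have equal length")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("helicity fraction outside [0, 1]")


@dataclass
class StateCall:
    """Classification of one frame by attached helices."""

    label: str  # e.g. "three-helix"
    attached: tuple[str, ...]


@dataclass
class IntermediateCall:
    """Replica-level unfolding summary.

    ``detachment_extension`` maps each helix that detached to the extension
    (Å) of its last crossing below the attachment threshold; helices still
    attached at the final frame are absent. ``state_labels`` is the
    compressed sequence of visited states in unfolding order.
    """

    state_labels: list[str]
    attached_sets: list[tuple[str, ...]]
    detachment_extension: dict[str, float]
    three_helix_set: tuple[str, ...] | None  # surviving trio, if visited

    def to_json(self, path: str) -> None:
        doc = asdict(self)
        doc["attached_sets"] = [list(s) for s in self.attached_sets]
        if doc["three_helix_set"] is not None:
            doc["three_helix_set"] = list(doc["three_helix_set"])
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


_NUMBER_WORDS = {
    0: "zero", 1: "one", 2: "two", 3: "three", 4: "four",
    5: "five", 6: "six", 7: "seven", 8: "eight", 9: "nine",
}


def _state_label(n_attached: int) -> str:
    return f"{_NUMBER_WORDS.get(n_attached, str(n_attached))}-helix"


def helicity_trace(
    frames: np.ndarray,
    detector: HelixDetectorParams | None = None,
) -> HelicityTrace:
    """Per-frame helical residue counts from the Cα-geometry detector."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    ext = np.linalg.norm(frames[:, -1] - frames[:, 0], axis=1)
    n_hel = np.array(
        [assign_helices(f, detector).per_residue_helical.sum() for f in frames],
        dtype=int,
    )
    return HelicityTrace(ext, n_hel, n_hel / n)


def _inter_helix_contacts(
    cmap: ContactMap,
    annotation: HelixAnnotation,
    structure_offsets: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Indices into the contact list for each helix pair with ≥ 1 contact."""
    labels = annotation.labels
    member = {}
    if structure_offsets is None:
        # annotation residue numbers are 1-based chain positions
        structure_offsets = {
            lab: np.arange(s - 1, e) for lab, s, e in annotation.segments
        }
    owner = {}
    for lab in labels:
        for off in structure_offsets[lab]:
            owner[int(off)] = lab
    by_pair: dict[tuple[str, str], list[int]] = {}
    for k, (i, j) in enumerate(cmap.pairs):
        a = owner.get(i)
        b = owner.get(j)
        if a is None or b is None or a == b:
            continue
        key = tuple(sorted((a, b), key=labels.index))
        by_pair.setdefault(key, []).append(k)
    return {k: np.array(v, dtype=int) for k, v in by_pair.items()}


def helix_pair_contact_fraction(
    frames: np.ndarray,
    cmap: ContactMap,
    annotation: HelixAnnotation,
    formed_factor: float = FORMED_FACTOR,
) -> dict[tuple[str, str], np.ndarray]:
    """Q(t) per helix pair: fraction of native inter-helix contacts formed.

    Pairs without native contacts are simply absent from the result (never
    reported as 0/0).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    groups = _inter_helix_contacts(cmap, annotation)
    pi = np.array([p[0] for p in cmap.pairs], dtype=int)
    pj = np.array([p[1] for p in cmap.pairs], dtype=int)
    cutoffs = formed_factor * cmap.native_distance
    out = {}
    d = np.linalg.norm(frames[:, pi, :] - frames[:, pj, :], axis=2)  # (frame, pair)
    formed = d < cutoffs[None, :]
    for key, idx in groups.items():
        out[key] = formed[:, idx].mean(axis=1)
    return out


def classify_state(
    q_by_pair: dict[tuple[str, str], float],
    annotation: HelixAnnotation,
    threshold: float = ATTACH_THRESHOLD,
) -> StateCall:
    """Label one frame by its attached helices.

    A helix is attached when its maximum Q against any partner is ≥ the
    threshold; the zero-helix state has no attached pair.
    """
    best: dict[str, float] = {lab: 0.0 for lab in annotation.labels}
    for (a, b), q in q_by_pair.items():
        q = float(q)
        best[a] = max(best[a], q)
        best[b] = max(best[b], q)
    attached = tuple(lab for lab in annotation.labels if best[lab] >= threshold)
    return StateCall(_state_label(len(attached)), attached)


def replica_state_sequence(
    q_traces: dict[tuple[str, str], np.ndarray],
    annotation: HelixAnnotation,
    extensions: np.ndarray,
    threshold: float = ATTACH_THRESHOLD,
) -> IntermediateCall:
    """Summarize a pulling replica into its unfolding state sequence.

    Detachment is hysteresis-free: each helix's detachment extension is the
    extension of its *last* crossing below the attachment threshold (helices
    whose Q never recovers afterwards). The attached count derived this way
    is monotone under load by construction; re-attachment after full
    detachment would show up as a missing detachment record.
    """
    extensions = np.asarray(extensions, dtype=float)
    labels = annotation.labels
    n_frames = len(extensions)
    best = np.zeros((n_frames, len(labels)))
    for (a, b), q in q_traces.items():
        ia, ib = labels.index(a), labels.index(b)
        best[:, ia] = np.maximum(best[:, ia], q)
        best[:, ib] = np.maximum(best[:, ib], q)

    detach_ext: dict[str, float] = {}
    for k, lab in enumerate(labels):
        attached = best[:, k] >= threshold
        if attached[-1] or not attached.any():
            continue  # still attached at the end, or never attached
        last_attached = int(np.max(np.where(attached)[0]))
        detach_ext[lab] = float(extensions[min(last_attached + 1, n_frames - 1)])

    current = [lab for k, lab in enumerate(labels) if best[0, k] >= threshold]
    states = [tuple(current)]
    # helices detaching at the same extension (same frame) leave together
    for ext in sorted(set(detach_ext.values())):
        leaving = {lab for lab, e in detach_ext.items() if e == ext}
        if not (leaving & set(current)):
            continue
        current = [x for x in current if x not in leaving]
        # a lone helix cannot be pairwise attached
        if len(current) == 1:
            current = []
        states.append(tuple(current))
    labels_seq = [_state_label(len(s)) for s in states]
    three = next((s for s in states if len(s) == 3), None)
    return IntermediateCall(labels_seq, states, detach_ext, three)


def pulling_state_census(
    topology,
    cmap: ContactMap,
    annotation: HelixAnnotation,
    n_replicas: int = 20,
    seed: int = 0,
    protocol=None,
    params=None,
    total_extension: float | None = None,
    equil_steps: int = 50_000,
    frame_stride: int = 4000,
) -> list[IntermediateCall]:
    """Run pulling replicas and classify each replica's unfolding pathway.

    Each replica is equilibrated with static springs, pulled at the
    protocol's velocity, and summarized by :func:`replica_state_sequence`.
    Replica ``r`` uses pulling seed ``seed + r``.
    """
    import dataclasses

    from .langevin_engine import LangevinParams
    from .pulling_smd import PullingProtocol, run_pulling

    params = params or LangevinParams()
    protocol = protocol or PullingProtocol()
    if total_extension is not None:
        protocol = dataclasses.replace(protocol, total_extension=total_extension)
    calls = []
    for rep in range(n_replicas):
        eq = run_pulling(
            topology,
            dataclasses.replace(protocol, velocity=0.0, total_extension=None),
            params,
            seed=seed + 9000 + rep,
            n_steps=equil_steps,
            record_stride=max(equil_steps // 10, 1),
        )
        tr = run_pulling(
            topology, protocol, params, seed=seed + rep,
            start_positions=eq.final_positions,
            record_stride=2000, frame_stride=frame_stride,
        )
        q = helix_pair_contact_fraction(tr.frames, cmap, annotation)
        calls.append(replica_state_sequence(q, annotation, tr.frame_extensions))
    return calls


def unfolding_events_from_pmf(
    rc: np.ndarray,
    values: np.ndarray,
    window: int = 3,
    min_rise: float = 2.0,
) -> list[float]:
    """Positions where the local slope exceeds ``min_rise`` × median slope.

    Works on a PMF or on any profile over a uniform rc grid (the same
    interface serves force traces). Contiguous super-threshold runs collapse
    to the position of their steepest point; events come back ordered by rc.
    """
    rc = np.asarray(rc, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(rc) != len(values):
        raise ValueError("rc and values length mismatch")
    if len(rc) < window + 1:
        return []
    slopes = (values[window:] - values[:-window]) / (rc[window:] - rc[:-window])
    mids = 0.5 * (rc[window:] + rc[:-window])
    med = np.median(slopes)
    if med <= 0:
        med = np.median(np.abs(slopes))
        if med == 0:
            return []
    above = slopes > min_rise * med
    events = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            events.append(float(mids[seg][np.argmax(slopes[seg])]))
            i = j + 1
        else:
            i += 1
    return events
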