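"""Ordered/disordered residue classification from confidence tracks.

Two independent signals feed the classification: the structure
predictor's per-residue plDDT (high = confident local geometry, and in
practice low plDDT marks intrinsic disorder) and a disorder predictor's
per-residue Z-score of structural order (ADOPT-style; high Z = ordered).
The consensus mask prefers the dedicated disorder predictor where
available, falling back to plDDT confidence, and every stratified count
downstream uses each species' own mask.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ResidueScoreTrack

__all__ = [
    "OrderMask",
    "classify_confidence",
    "classify_order",
    "consensus_mask",
    "DEFAULT_PLDDT_THRESHOLD",
    "DEFAULT_ADOPT_Z_THRESHOLD",
]

#: plDDT at or above this is "confident" (standard predictor practice;
#: below it local geometry is unreliable and usually disordered).
DEFAULT_PLDDT_THRESHOLD = 70.0
#: order Z-score at or above this is "ordered".
DEFAULT_ADOPT_Z_THRESHOLD = 3.0


@dataclass(frozen=True)
class OrderMask:
    """Per-residue order and confidence states for one sequence."""

    id: str
    order_state: tuple[str, ...]        # "ordered" | "disordered"
    confidence_state: tuple[str, ...]   # "confident" | "low"
    plddt_threshold: float
    adopt_z_threshold: float
    policy: str = "adopt_first"

    def __post_init__(self):
        if len(self.order_state) != len(self.confidence_state):
            raise ValueError("order and confidence tracks differ in length")

    def __len__(self) -> int:
        return len(self.order_state)


def classify_confidence(track: ResidueScoreTrack,
                        threshold: float = DEFAULT_PLDDT_THRESHOLD) -> list[str]:
    """Per-residue "confident"/"low" from a plDDT track (confident iff ≥)."""
    if track.kind != "plddt":
        raise ValueError(f"expected a plddt track, got {track.kind!r}")
    return ["confident" if v >= threshold else "low" for v in track.values()]


def classify_order(track: ResidueScoreTrack,
                   threshold: float = DEFAULT_ADOPT_Z_THRESHOLD) -> list[str]:
    """Per-residue "ordered"/"disordered" from an order Z-score track
    (ordered iff ≥)."""
    if track.kind != "adopt_z":
        raise ValueError(f"expected an adopt_z track, got {track.kind!r}")
    return ["ordered" if v >= threshold else "disordered" for v in track.values()]


def consensus_mask(
    track_id: str,
    confidence_states: list[str],
    order_states: list[str] | None = None,
    policy: str = "adopt_first",
    plddt_threshold: float = DEFAULT_PLDDT_THRESHOLD,
    adopt_z_threshold: float = DEFAULT_ADOPT_Z_THRESHOLD,
) -> OrderMask:
    """Combine confidence and order tracks into one mask.

    Policies:
      * ``adopt_first`` (default): the disorder predictor decides where a
        Z-track exists; otherwise "confident" maps to ordered and "low"
        to disordered.
      * ``plddt_only``: ignore the Z-track entirely.
    """
    if order_states is not None and len(order_states) != len(confidence_states):
        raise ValueError(
            f"track length mismatch: {len(order_states)} order vs "
            f"{len(confidence_states)} confidence states"
        )
    fallback = [
        "ordered" if c == "confident" else "disordered" for c in confidence_states
    ]
    if policy == "plddt_only" or order_states is None:
        order = fallback
    elif policy == "adopt_first":
        order = list(order_states)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return OrderMask(
        id=track_id,
        order_state=tuple(order),
        confidence_state=tuple(confidence_states),
        plddt_threshold=plddt_threshold,
        adopt_z_threshold=adopt_z_threshold,
        policy=policy if order_states is not None else "plddt_fallback",
    )
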