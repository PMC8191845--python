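"""Response and marathon-performance group assignment.

Training response is graded *relative to peers of similar starting
fitness*: the cohort is cut into ten deciles of the block-1 best 10-km
velocity, and within each decile the 33.3rd/66.6th percentiles of Δv10
split subjects into low / moderate / high response terciles.  Because the
split is rank-based within the decile, a subject with a negative Δv10 can
still land in the high-response group of a decile where everyone slowed
down.

Marathon performance groups are plain cohort-wide terciles of the
marathon time T_mp (fast = lowest times).

Percentiles use linear interpolation between order statistics; values
exactly at a cut point go to the lower group.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

RESPONSE_LABELS = ("low", "moderate", "high")
MARATHON_LABELS = ("fast", "medium", "slow")  # by increasing T_mp
TERCILE_Q = (33.3, 66.6)


def velocity_deciles(v10_tb1: np.ndarray) -> np.ndarray:
    """Decile index (0..9) per subject from the v10 block-1 distribution.

    Edges sit at the 10th..90th percentiles; intervals are right-closed,
    so a value exactly on an edge belongs to the lower decile.  Degenerate
    (tied) edges collapse, leaving upper deciles empty.
    """
    v = np.asarray(v10_tb1, dtype=float)
    edges = np.percentile(v, np.arange(10, 100, 10))
    return np.searchsorted(edges, v, side="left").astype(int)


def _tercile_labels(x: np.ndarray, labels: tuple[str, str, str]) -> np.ndarray:
    lo, hi = np.percentile(x, TERCILE_Q)
    out = np.where(x <= lo, labels[0], np.where(x <= hi, labels[1], labels[2]))
    return out


def response_groups(
    delta_v10: np.ndarray, deciles: np.ndarray, min_decile_size: int = 3
) -> np.ndarray:
    """Low/moderate/high response label per subject.

    Terciles of Δv10 are computed separately inside each velocity decile;
    deciles with fewer than ``min_decile_size`` subjects fall back to the
    cohort-wide tercile cuts (logged).
    """
    dv = np.asarray(delta_v10, dtype=float)
    deciles = np.asarray(deciles)
    out = np.empty(len(dv), dtype=object)
    global_labels = _tercile_labels(dv, RESPONSE_LABELS)
    for d in np.unique(deciles):
        mask = deciles == d
        if mask.sum() < min_decile_size:
            log.info("decile %d has %d subjects; using global tercile cuts", d, mask.sum())
            out[mask] = global_labels[mask]
        else:
            out[mask] = _tercile_labels(dv[mask], RESPONSE_LABELS)
    return out.astype(str)


def marathon_groups(t_mp: np.ndarray) -> np.ndarray:
    """Fast/medium/slow marathon group per subject from T_mp terciles
    (lower time = faster)."""
    return _tercile_labels(np.asarray(t_mp, dtype=float), MARATHON_LABELS).astype(str)


def assign_groups(v10_tb1, delta_v10, t_mp) -> dict[str, np.ndarray]:
    """Full group assignment for a filtered cohort."""
    deciles = velocity_deciles(np.asarray(v10_tb1))
    return {
        "velocity_decile": deciles,
        "response": response_groups(np.asarray(delta_v10), deciles),
        "marathon": marathon_groups(np.asarray(t_mp)),
    }
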