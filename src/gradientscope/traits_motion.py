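"""Questionnaire scoring (AQ, GSQ) and scan-motion summaries (FD, DVARS).

AQ: 50 items answered on a 4-level agreement scale, binarized so each item
contributes 1 when the response falls on its keyed (autistic-direction)
pole; totals range 0–50. The per-item key is supplied as data, not
hard-coded.

GSQ: 42 items on a 0–4 frequency scale — six items for each of seven sensory
modalities, split evenly between hyper- and hyposensitivity; totals range
0–168 (84 per polarity subscale, 144 with one modality excluded).

FD is the mean over the twelve realignment parameters of the median absolute
frame-to-frame derivative; DVARS is the RMS over voxels of the temporal
derivative, summarized per subject as the mean over volume pairs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GSQ_MODALITIES",
    "gsq_item_table",
    "score_aq",
    "score_gsq",
    "compute_fd",
    "compute_dvars",
]

N_AQ_ITEMS = 50
N_GSQ_ITEMS = 42
GSQ_MODALITIES = (
    "vision", "hearing", "olfaction", "taste", "touch",
    "proprioception", "vestibular",
)

# AQ response coding: 0 = definitely agree, 1 = slightly agree,
# 2 = slightly disagree, 3 = definitely disagree.
_AGREE = frozenset({0, 1})
_DISAGREE = frozenset({2, 3})


def gsq_item_table() -> pd.DataFrame:
    """Canonical GSQ item metadata: 7 modalities × 3 hyper + 3 hypo items.

    Columns: item (0-based), modality, polarity. The real instrument's item
    ordering is not reproduced; scoring depends only on this structure.
    """
    rows = []
    item = 0
    for modality in GSQ_MODALITIES:
        for polarity in ("hyper",) * 3 + ("hypo",) * 3:
            rows.append(dict(item=item, modality=modality, polarity=polarity))
            item += 1
    return pd.DataFrame(rows)


def score_aq(responses: Sequence[int], key: Sequence[str]) -> int:
    """Binarized AQ total in [0, 50].

    ``responses`` are the 50 item answers coded 0–3 (definitely agree …
    definitely disagree); ``key`` gives each item's autistic-direction pole
    ("agree" or "disagree"). An item scores 1 iff the response (slightly or
    definitely) falls on the keyed pole. Missing responses raise — no
    imputation.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.size != N_AQ_ITEMS:
        raise ValueError(f"AQ needs exactly {N_AQ_ITEMS} responses, got {resp.size}")
    if np.isnan(resp).any():
        missing = np.flatnonzero(np.isnan(resp)).tolist()
        raise ValueError(f"missing AQ responses at items {missing}")
    if not np.isin(resp, [0, 1, 2, 3]).all():
        raise ValueError("AQ responses must be integers in 0..3")
    if len(key) != N_AQ_ITEMS:
        raise ValueError(f"AQ key needs {N_AQ_ITEMS} entries")
    total = 0
    for r, k in zip(resp.astype(int), key):
        if k == "agree":
            total += int(r in _AGREE)
        elif k == "disagree":
            total += int(r in _DISAGREE)
        else:
            raise ValueError(f"key entries must be 'agree' or 'disagree', got {k!r}")
    return total


def score_gsq(responses: Sequence[int], items: pd.DataFrame | None = None,
              exclude_modalities: Iterable[str] = (),
              polarity: str = "both") -> int:
    """GSQ total: sum of 0–4 item responses over the retained items.

    ``exclude_modalities`` drops whole sensory modalities (vision-removed
    totals max at 144); ``polarity`` restricts to the "hyper" or "hypo"
    subscale (max 84 each) or keeps "both".
    """
    items = items if items is not None else gsq_item_table()
    resp = np.asarray(responses, dtype=float)
    if resp.size != N_GSQ_ITEMS:
        raise ValueError(f"GSQ needs exactly {N_GSQ_ITEMS} responses, got {resp.size}")
    if np.isnan(resp).any():
        missing = np.flatnonzero(np.isnan(resp)).tolist()
        raise ValueError(f"missing GSQ responses at items {missing}")
    if not np.isin(resp, [0, 1, 2, 3, 4]).all():
        raise ValueError("GSQ responses must be integers in 0..4")
    if polarity not in ("both", "hyper", "hypo"):
        raise ValueError("polarity must be 'both', 'hyper' or 'hypo'")
    excluded = set(exclude_modalities)
    unknown = excluded - set(GSQ_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    keep = ~items["modality"].isin(excluded)
    if polarity != "both":
        keep &= items["polarity"] == polarity
    return int(resp[items.loc[keep, "item"].to_numpy()].sum())


def compute_fd(realignment: np.ndarray, conventional: bool = False) -> float:
    """Framewise-displacement summary from T × 12 realignment traces.

    Default: per parameter, the median of |frame-to-frame derivative| over
    time, then the mean of the twelve medians. ``conventional=True`` instead
    returns the time-mean of the per-frame sum of absolute derivatives
    (the usual framewise-displacement definition).
    """
    traces = np.asarray(realignment, dtype=float)
    if traces.ndim != 2 or traces.shape[1] != 12:
        raise ValueError(f"realignment traces must be T × 12, got {traces.shape}")
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    deriv = np.abs(np.diff(traces, axis=0))
    if conventional:
        return float(deriv.sum(axis=1).mean())
    return float(np.median(deriv, axis=0).mean())


def compute_dvars(ts: np.ndarray) -> float:
    """DVARS summary from T × V brain-masked time courses.

    Per volume pair, the RMS over voxels of the temporal derivative; the
    subject summary is the mean over volume pairs.
    """
    data = np.asarray(ts, dtype=float)
    if data.ndim != 2:
        raise ValueError("time courses must be T × V")
    if data.shape[1] == 0:
        raise ValueError("empty brain mask (no voxels)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    deriv = np.diff(data, axis=0)
    per_pair = np.sqrt(np.mean(deriv**2, axis=1))
    return float(per_pair.mean())
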