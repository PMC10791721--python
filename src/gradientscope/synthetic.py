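"""Synthetic cohorts with a planted gradient geometry and trait coupling.

The generator emulates the statistical structure the analysis assumes, not
realistic BOLD data: parcels live on a latent 3-axis embedding whose first
axis runs from visual to default-mode networks; edge strength decays
exponentially with latent distance (plus a same-network bonus and Gaussian
edge noise). A sensory-sensitivity-like trait (GSQ) expands each subject's
axis-1 geometry multiplicatively, planting a chosen rank correlation between
the trait and the visual–default separation, while an AQ-like trait couples
to the geometry only through its correlation with GSQ. Questionnaire item
responses are generated so that scoring reproduces the drawn totals exactly,
and motion traces are random walks calibrated to a target framewise
displacement.

All randomness flows from one root seed through `numpy.random.SeedSequence`
substreams (traits, then one child per subject).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ConnectivityMatrix,
    NetworkPartition,
    write_matrix,
    write_partition,
    write_participants,
)
from .traits_motion import (
    GSQ_MODALITIES,
    compute_dvars,
    compute_fd,
    gsq_item_table,
    score_aq,
    score_gsq,
)

__all__ = [
    "NETWORK_NAMES",
    "CohortSpec",
    "Cohort",
    "apply_exclusions",
    "make_partition",
    "simulate_traits",
    "simulate_connectome",
    "simulate_motion",
    "simulate_cohort",
    "generate_cohort_files",
]

# Canonical 7-network scheme, in rank order along the principal gradient.
NETWORK_NAMES = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Cont",
                 "Limbic", "Default")
# Parcel counts of the 400-parcel / 7-network atlas, same order.
_ATLAS_400_SIZES = (61, 77, 46, 47, 52, 26, 91)
# Network centres along the latent unimodal → transmodal axis (axis 1);
# axes 2–3 carry minor, stationary structure.
_BASE_AXIS1 = (-0.90, -0.60, -0.30, 0.00, 0.30, 0.60, 0.90)
_BASE_AXIS2 = (0.09, -0.075, 0.03, -0.03, 0.015, 0.045, -0.015)
_BASE_AXIS3 = (-0.03, 0.06, -0.045, 0.075, -0.015, 0.03, 0.00)
# Anchor positions of the two connectivity poles (sensory and transmodal).
_POLES = (-1.0, 1.0)

_MEDIAN_ABS_Z = 0.6744897501960817  # Phi^{-1}(0.75): median of |N(0,1)|


def apply_exclusions(n_recruited: int, exclusions: Sequence[int]) -> int:
    """Retained sample size after subtracting exclusion counts."""
    excl = [int(e) for e in exclusions]
    if any(e < 0 for e in excl) or n_recruited < 0:
        raise ValueError("counts must be non-negative")
    retained = int(n_recruited) - sum(excl)
    if retained < 0:
        raise ValueError("exclusions exceed the recruited sample")
    return retained


def _proportional_sizes(n_parcels: int, weights: Sequence[int]) -> tuple[int, ...]:
    """Largest-remainder allocation of n_parcels across networks (each >= 1)."""
    weights = np.asarray(weights, dtype=float)
    quota = n_parcels * weights / weights.sum()
    sizes = np.floor(quota).astype(int)
    sizes = np.maximum(sizes, 1)
    while sizes.sum() > n_parcels:
        sizes[np.argmax(sizes)] -= 1
    rem = quota - np.floor(quota)
    while sizes.sum() < n_parcels:
        order = np.argsort(-rem)
        for i in order:
            if sizes.sum() == n_parcels:
                break
            sizes[i] += 1
            rem[i] = -1
    return tuple(int(s) for s in sizes)


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    Defaults mirror the reference study: 370 subjects, 400 parcels in 7
    networks, GSQ-like totals with mean 50.1 / SD 18.2, AQ-like totals with
    mean 19.6 / SD 5.3, a study-scale planted trait–separation rank
    correlation of 0.168, and motion calibrated to a 0.03 mm framewise
    displacement.
    """

    n_subjects: int = 370
    n_parcels: int = 400
    partition_sizes: tuple[int, ...] = ()
    planted_spearman: float = 0.168
    beta_expand: float = 0.18
    base_expansion: float = 0.85
    expansion_range: tuple[float, float] = (0.5, 1.15)
    transfer_attenuation: float = 0.85
    sigma_parcel: float = 0.015
    sigma_edge: float = 0.015
    local_amp: float = 0.25
    local_scale: float = 0.1
    pole_amp: float = 0.7
    pole_scale: float = 0.8
    network_width: float = 0.45
    gsq_mean: float = 50.1
    gsq_sd: float = 18.2
    aq_mean: float = 19.6
    aq_sd: float = 5.3
    trait_corr: float = 0.25
    age_mean: float = 21.05
    age_sd: float = 1.29
    p_male: float = 99 / 370
    n_timepoints: int = 232
    n_voxels: int = 120
    target_fd: float = 0.03
    target_dvars: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.partition_sizes:
            self.partition_sizes = _proportional_sizes(self.n_parcels,
                                                       _ATLAS_400_SIZES)
        if len(self.partition_sizes) != len(NETWORK_NAMES):
            raise ValueError(f"need {len(NETWORK_NAMES)} network sizes")
        if sum(self.partition_sizes) != self.n_parcels:
            raise ValueError("partition sizes must sum to n_parcels")
        if min(self.sigma_parcel, self.sigma_edge) <= 0:
            raise ValueError("noise scales must be positive")
        if min(self.local_scale, self.pole_scale) <= 0:
            raise ValueError("connectivity decay scales must be positive")
        if not 0 < self.transfer_attenuation <= 1:
            raise ValueError("transfer_attenuation must lie in (0, 1]")
        if abs(self.planted_spearman) > 1:
            raise ValueError("|planted_spearman| must be <= 1")
        if abs(self.trait_corr) > 1:
            raise ValueError("|trait_corr| must be <= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["partition_sizes"] = list(self.partition_sizes)
        return d


@dataclass
class Cohort:
    """A fully simulated cohort with its generating ground truth."""

    spec: CohortSpec
    participants: pd.DataFrame
    matrices: list[ConnectivityMatrix]
    partition: NetworkPartition
    aq_items: pd.DataFrame
    gsq_items: pd.DataFrame
    aq_key: tuple[str, ...]
    ground_truth: dict


def make_partition(spec: CohortSpec) -> NetworkPartition:
    parcel_ids, networks = [], []
    i = 0
    for net, size in zip(NETWORK_NAMES, spec.partition_sizes):
        for _ in range(size):
            parcel_ids.append(f"parcel_{i:04d}")
            networks.append(net)
            i += 1
    return NetworkPartition(parcel_ids=tuple(parcel_ids),
                            network_of=tuple(networks),
                            network_order=NETWORK_NAMES)


def _truncated_bivariate(rng: np.random.Generator, n: int, corr: float,
                         mean_a: float, sd_a: float, lo_a: float, hi_a: float,
                         mean_b: float, sd_b: float, lo_b: float, hi_b: float,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Correlated normal pairs, rejection-sampled into their closed ranges."""
    out_a = np.empty(n)
    out_b = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        z1 = rng.standard_normal(m)
        z2 = corr * z1 + math.sqrt(1 - corr**2) * rng.standard_normal(m)
        a = mean_a + sd_a * z1
        b = mean_b + sd_b * z2
        ok = (a >= lo_a) & (a <= hi_a) & (b >= lo_b) & (b <= hi_b)
        take = min(int(ok.sum()), n - filled)
        out_a[filled:filled + take] = a[ok][:take]
        out_b[filled:filled + take] = b[ok][:take]
        filled += take
    return out_a, out_b


def _gsq_responses(rng: np.random.Generator, total: int) -> np.ndarray:
    """Uniform random 42-item response vector (0–4 each) with the given sum."""
    return rng.multivariate_hypergeometric([4] * 42, total).astype(int)


def _aq_responses(rng: np.random.Generator, total: int,
                  key: Sequence[str]) -> np.ndarray:
    """Random 50-item AQ responses whose binarized score equals ``total``."""
    scored = rng.choice(50, size=total, replace=False)
    resp = np.empty(50, dtype=int)
    halves = rng.integers(0, 2, size=50)  # slightly vs definitely
    for i in range(50):
        on_pole = i in set(scored.tolist())
        agree_keyed = key[i] == "agree"
        # agree pole responses are {0,1}; disagree pole {2,3}
        pole_agree = on_pole if agree_keyed else not on_pole
        resp[i] = halves[i] if pole_agree else 2 + halves[i]
    return resp


def simulate_traits(spec: CohortSpec, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               tuple[str, ...]]:
    """Draw trait totals, matching item responses, age and gender.

    Returns (participants, aq_item_responses, gsq_item_responses, aq_key).
    Totals are correlated truncated normals within [0, 50] (AQ) and [0, 168]
    (GSQ); item responses are generated so that scoring reproduces each
    subject's total exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    gsq_raw, aq_raw = _truncated_bivariate(
        rng, n, spec.trait_corr,
        spec.gsq_mean, spec.gsq_sd, 0, 168,
        spec.aq_mean, spec.aq_sd, 0, 50,
    )
    gsq_total = np.rint(gsq_raw).astype(int)
    aq_total = np.rint(aq_raw).astype(int)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 18, 26).round(1)
    gender = rng.binomial(1, spec.p_male, size=n)  # 1 = male

    aq_key = tuple(rng.choice(["agree", "disagree"], size=50))
    items = gsq_item_table()
    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    aq_rows, gsq_rows, rows = [], [], []
    for i, sid in enumerate(subject_ids):
        aq_resp = _aq_responses(rng, aq_total[i], aq_key)
        gsq_resp = _gsq_responses(rng, gsq_total[i])
        assert score_aq(aq_resp, aq_key) == aq_total[i]
        assert score_gsq(gsq_resp, items) == gsq_total[i]
        aq_rows.append(dict(subject_id=sid,
                            **{f"aq_{j:02d}": int(v) for j, v in enumerate(aq_resp)}))
        gsq_rows.append(dict(subject_id=sid,
                             **{f"gsq_{j:02d}": int(v) for j, v in enumerate(gsq_resp)}))
        row = dict(subject_id=sid, aq_total=int(aq_total[i]),
                   gsq_total=int(gsq_total[i]),
                   gsq_hyper=score_gsq(gsq_resp, items, polarity="hyper"),
                   gsq_hypo=score_gsq(gsq_resp, items, polarity="hypo"),
                   gsq_no_vision=score_gsq(gsq_resp, items,
                                           exclude_modalities=("vision",)),
                   age=float(age[i]), gender=int(gender[i]))
        for mod in GSQ_MODALITIES:
            other = tuple(m for m in GSQ_MODALITIES if m != mod)
            row[f"gsq_{mod}"] = score_gsq(gsq_resp, items, exclude_modalities=other)
        rows.append(row)
    return (pd.DataFrame(rows), pd.DataFrame(aq_rows), pd.DataFrame(gsq_rows),
            aq_key)


def _base_coords(spec: CohortSpec) -> np.ndarray:
    """Latent parcel coordinates (P × 3): a continuous hierarchy.

    Each network's parcels are spread evenly over an interval of width
    ``network_width`` around the network centre on axis 1, so the axis forms
    a connected chain from the sensory to the transmodal end; axes 2–3 hold
    the small stationary network offsets.
    """
    axis1 = np.concatenate([
        c + spec.network_width * (np.linspace(-0.5, 0.5, s) if s > 1
                                  else np.zeros(1))
        for c, s in zip(_BASE_AXIS1, spec.partition_sizes)
    ])
    axis2 = np.repeat(_BASE_AXIS2, spec.partition_sizes)
    axis3 = np.repeat(_BASE_AXIS3, spec.partition_sizes)
    return np.column_stack([axis1, axis2, axis3])


def simulate_connectome(expansion: float, spec: CohortSpec,
                        rng: np.random.Generator,
                        parcel_ids: tuple[str, ...] = ()) -> ConnectivityMatrix:
    """One subject's correlation matrix from the latent two-pole geometry.

    Axis-1 positions are multiplied by ``expansion`` while the two
    connectivity poles stay anchored at ±1; axes 2–3 are stationary.
    Correlations combine a short-range component, ``local_amp ·
    exp(−d/local_scale)``, with graded connectivity to both poles,
    ``pole_amp · (p_i p_j + q_i q_j)`` where p and q decay with axis-1
    distance from the sensory and transmodal anchors at rate ``pole_scale``.
    Stretching the axis weakens mid-hierarchy pole coupling, which the
    sparsified cosine embedding reads out as a wider gradient. Gaussian edge
    noise is added, and the matrix is clipped to [−0.99, 0.99], symmetrized,
    unit diagonal.
    """
    if expansion <= 0:
        raise ValueError("expansion factor must be positive")
    coords = _base_coords(spec).copy()
    coords[:, 0] *= expansion
    coords += rng.normal(0.0, spec.sigma_parcel, size=coords.shape)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    x = coords[:, 0]
    p = np.exp(-np.abs(x - _POLES[0]) / spec.pole_scale)
    q = np.exp(-np.abs(x - _POLES[1]) / spec.pole_scale)
    r = (spec.local_amp * np.exp(-d / spec.local_scale)
         + spec.pole_amp * (np.outer(p, p) + np.outer(q, q)))
    noise = rng.normal(0.0, spec.sigma_edge, size=r.shape)
    r += (noise + noise.T) / 2.0
    r = np.clip((r + r.T) / 2.0, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, parcel_ids=parcel_ids)


def simulate_motion(spec: CohortSpec, rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk realignment traces and masked voxel series.

    Step size is calibrated so the median |derivative| of each of the 12
    parameters equals ``target_fd`` (median of |N(0, s)| = 0.6745·s); voxel
    series are white noise scaled so the expected volume-to-volume RMS
    derivative equals ``target_dvars``.
    """
    if spec.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    step = spec.target_fd / _MEDIAN_ABS_Z
    steps = rng.normal(0.0, step, size=(spec.n_timepoints - 1, 12))
    traces = np.vstack([np.zeros(12), np.cumsum(steps, axis=0)])
    sigma_vox = spec.target_dvars / math.sqrt(2.0)
    voxels = rng.normal(0.0, sigma_vox, size=(spec.n_timepoints, spec.n_voxels))
    return traces, voxels


def simulate_cohort(spec: CohortSpec, seed: int | None = None,
                    include_motion: bool = True) -> Cohort:
    """Simulate a complete cohort (traits, connectomes, optionally motion).

    ``spec.planted_spearman`` is the target rank correlation between the
    GSQ-like trait and the measured visual–default separation. The expansion
    latent mixes the standardized trait with independent noise at the
    Pearson weight 2·sin(π·ρ/6) (the bivariate-normal value whose population
    Spearman is ρ), divided by the generator's fixed measurement-transfer
    constant ``transfer_attenuation`` so that the planted correlation lands
    on the pipeline's measured metric rather than on the unobserved latent.
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    trait_ss, *subject_ss = root.spawn(1 + spec.n_subjects)
    trait_rng = np.random.default_rng(trait_ss)
    participants, aq_items, gsq_items, aq_key = simulate_traits(spec, rng=trait_rng)
    partition = make_partition(spec)

    gsq = participants["gsq_total"].to_numpy(dtype=float)
    z = (gsq - gsq.mean()) / (gsq.std(ddof=0) or 1.0)
    a = 2.0 * math.sin(math.pi * spec.planted_spearman / 6.0)
    a = float(np.clip(a / spec.transfer_attenuation, -0.99, 0.99))
    eps = trait_rng.standard_normal(spec.n_subjects)
    w = a * z + math.sqrt(max(0.0, 1.0 - a**2)) * eps
    lo, hi = spec.expansion_range
    expansion = np.clip(spec.base_expansion * (1.0 + spec.beta_expand * w), lo, hi)

    matrices: list[ConnectivityMatrix] = []
    fd, dvars = np.zeros(spec.n_subjects), np.zeros(spec.n_subjects)
    for i, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        matrices.append(simulate_connectome(float(expansion[i]), spec, rng,
                                            parcel_ids=partition.parcel_ids))
        if include_motion:
            traces, voxels = simulate_motion(spec, rng)
            fd[i] = compute_fd(traces)
            dvars[i] = compute_dvars(voxels)
    if include_motion:
        participants = participants.assign(fd=fd, dvars=dvars)
    ground_truth = dict(
        planted_spearman=spec.planted_spearman,
        expansion=expansion.tolist(),
        pearson_weight=a,
        seed=int(spec.seed if seed is None else seed),
    )
    return Cohort(spec=spec, participants=participants, matrices=matrices,
                  partition=partition, aq_items=aq_items, gsq_items=gsq_items,
                  aq_key=aq_key, ground_truth=ground_truth)


def generate_cohort_files(spec: CohortSpec, out_dir: str | Path,
                          seed: int | None = None,
                          include_motion: bool = True) -> Path:
    """Write the full on-disk layout the pipeline consumes.

    ``out_dir/`` gets: matrices/sub-XXXX.tsv, partition.tsv,
    participants.csv, aq_items.csv, gsq_items.csv, aq_key.csv, optional
    motion/sub-XXXX.tsv traces, and manifest.json with the ground-truth
    parameters. Returns the output directory.
    """
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec, seed=seed, include_motion=include_motion)
    write_partition(cohort.partition, out / "partition.tsv")
    write_participants(cohort.participants, out / "participants.csv")
    cohort.aq_items.to_csv(out / "aq_items.csv", index=False)
    cohort.gsq_items.to_csv(out / "gsq_items.csv", index=False)
    pd.DataFrame({"item": range(50), "keyed": list(cohort.aq_key)}).to_csv(
        out / "aq_key.csv", index=False)
    for sid, m in zip(cohort.participants["subject_id"], cohort.matrices):
        write_matrix(m, out / "matrices" / f"{sid}.tsv")
    manifest = dict(spec=spec.to_dict(), ground_truth=cohort.ground_truth)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
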