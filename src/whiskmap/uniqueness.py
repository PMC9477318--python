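"""Uniqueness testing of triplet mappings.

A triplet of base signals maps the contact-point space into a 3D signal
space. The mapping is *unique* (invertible) when no two distant contact
points produce the same signal triplet. Two complementary tests are run:

1. A nonlinear function approximator (a small feed-forward network) is fit
   from the triplet to (r, θ, φ). If the mapping is single-valued the network
   can represent it and held-out errors are small; a many-to-one mapping
   forces the fit to average distinct branches, inflating held-out error.
2. A direct geometric overlap scan: pairs of records that are mutually close
   in standardized signal space but far apart in contact space are counted.
   Any such pair is a counterexample to invertibility. This is the
   automatable equivalent of checking that no two monochromatic surfaces of
   the mapping "solid" overlap.

A triplet is declared unique only when all three held-out error medians fall
below their thresholds *and* the overlap count is zero, unanimously across
the approximator seeds; disagreement between seeds is reported as
inconclusive, never silently unique.

Uniqueness can hold only on a sub-region: after excluding large deflections
(ELD), or restricted to concave-forward (CF) or concave-backward (CB)
contacts, or both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .mapping import MappingTable, TripletSpec, contact_xyz, enumerate_triplets

__all__ = [
    "UniquenessThresholds",
    "UniquenessReport",
    "enumerate_triplets",
    "region_filter",
    "overlap_scan",
    "test_uniqueness",
    "uniqueness_survey",
    "REGION_CONDITIONS",
]

REGION_CONDITIONS = ("All", "ELD", "CF", "CB", "ELD-CF", "ELD-CB")


@dataclass(frozen=True)
class UniquenessThresholds:
    """Held-out error thresholds (20 mm whisker scale) and overlap radii.

    ``eps_sig`` is in units of the table's median nearest-neighbour spacing in
    standardized signal space; ``eps_cp_mm`` is the Cartesian contact-point
    distance beyond which two signal-space neighbours count as an overlap
    (several grid steps, so adjacent grid records never trigger it).
    """

    median_r_mm: float = 1.0
    median_angle_deg: float = 2.0
    eps_sig: float = 0.2
    eps_cp_mm: float = 5.0


@dataclass
class UniquenessReport:
    triplet: TripletSpec
    verdict: str                      # unique | not-unique | inconclusive
    condition: str
    median_abs_errors: dict           # r_mm, theta_deg, phi_deg
    p95_abs_errors: dict
    overlap_count: int
    n_records: int
    seed_verdicts: list = field(default_factory=list)
    thresholds: UniquenessThresholds = field(default_factory=UniquenessThresholds)

    def to_dict(self) -> dict:
        return {
            "triplet": list(self.triplet.names),
            "verdict": self.verdict,
            "condition": self.condition,
            "median_abs_errors": self.median_abs_errors,
            "p95_abs_errors": self.p95_abs_errors,
            "overlap_count": self.overlap_count,
            "n_records": self.n_records,
            "seed_verdicts": self.seed_verdicts,
            "thresholds": {
                "median_r_mm": self.thresholds.median_r_mm,
                "median_angle_deg": self.thresholds.median_angle_deg,
                "eps_sig": self.thresholds.eps_sig,
                "eps_cp_mm": self.thresholds.eps_cp_mm,
            },
        }


def region_filter(table: MappingTable, condition: str) -> MappingTable:
    """Subset of a table matching a region condition.

    ELD drops large-deflection records; CF keeps azimuths ≤ 0 (deflections
    against the intrinsic curvature), CB azimuths > 0. Conditions compose
    with a hyphen (``ELD-CF``). ``All`` is the identity.
    """
    if condition not in REGION_CONDITIONS:
        raise ParameterError(f"unknown region condition {condition!r}")
    df = table.df
    mask = np.ones(len(df), bool)
    for part in condition.split("-"):
        if part == "All":
            continue
        if part == "ELD":
            mask &= (df["region"] != "ld").to_numpy()
        elif part == "CF":
            mask &= (df["theta_deg"] <= 0).to_numpy()
        elif part == "CB":
            mask &= (df["theta_deg"] > 0).to_numpy()
    sub = MappingTable(df[mask], table.meta)
    return sub


def overlap_scan(table: MappingTable, spec: TripletSpec,
                 thresholds: UniquenessThresholds | None = None,
                 eps_sig_abs: float | None = None) -> int:
    """Count signal-space neighbour pairs with distant contact points.

    Exhaustive over all pairs within ``eps_sig`` (KD-tree range query); on a
    unique mapping neighbouring signals imply neighbouring contact points, so
    the count is zero.
    """
    from scipy.spatial import cKDTree

    thr = thresholds or UniquenessThresholds()
    sub = table.retained().reset_index(drop=True)
    X, _ = table._embedding(spec, sub)
    tree = cKDTree(X)
    if eps_sig_abs is None:
        d_nn, _ = tree.query(X, k=min(2, len(X)))
        eps_sig_abs = thr.eps_sig * float(np.median(d_nn[:, -1]))
    pairs = tree.query_pairs(eps_sig_abs, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    xyz = contact_xyz(sub)
    gap = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    return int(np.sum(gap > thr.eps_cp_mm))


def _fit_errors(X, y, seed: int, train_frac: float):
    """Held-out absolute errors of one approximator fit; None on failure."""
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    rng = np.random.default_rng(seed)
    n = len(X)
    order = rng.permutation(n)
    n_train = int(train_frac * n)
    tr, te = order[:n_train], order[n_train:]
    mu, sd = y[tr].mean(axis=0), y[tr].std(axis=0)
    sd[sd < 1e-12] = 1.0
    net = MLPRegressor(hidden_layer_sizes=(64, 64), activation="tanh",
                       solver="adam", learning_rate_init=3e-3, max_iter=600,
                       early_stopping=True, n_iter_no_change=20, tol=1e-6,
                       random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        net.fit(X[tr], (y[tr] - mu) / sd)
    pred = net.predict(X[te]) * sd + mu
    if not np.isfinite(pred).all():
        return None
    return np.abs(pred - y[te])


def test_uniqueness(table: MappingTable, spec: TripletSpec,
                    region: str = "All",
                    thresholds: UniquenessThresholds | None = None,
                    seeds=(0, 1, 2), train_frac: float = 0.75,
                    min_records: int = 1000) -> UniquenessReport:
    """Dual-evidence uniqueness test of one triplet on one region."""
    thr = thresholds or UniquenessThresholds()
    sub_table = region_filter(table, region)
    sub = sub_table.retained().reset_index(drop=True)
    if len(sub) < min_records:
        raise InsufficientDataError(
            f"{len(sub)} records in region {region}; need >= {min_records}")
    X, _ = sub_table._embedding(spec, sub)
    y = sub[["r_mm", "theta_deg", "phi_deg"]].to_numpy(float)
    n_overlap = overlap_scan(sub_table, spec, thr)

    seed_verdicts = []
    med_all, p95_all = [], []
    for seed in seeds:
        err = _fit_errors(X, y, seed, train_frac)
        if err is None:
            seed_verdicts.append("inconclusive")
            continue
        med = np.median(err, axis=0)
        med_all.append(med)
        p95_all.append(np.percentile(err, 95, axis=0))
        ok = (med[0] < thr.median_r_mm and med[1] < thr.median_angle_deg
              and med[2] < thr.median_angle_deg and n_overlap == 0)
        seed_verdicts.append("unique" if ok else "not-unique")

    if len(set(seed_verdicts)) == 1 and seed_verdicts[0] != "inconclusive":
        verdict = seed_verdicts[0]
    else:
        verdict = "inconclusive"
    med = np.median(np.array(med_all), axis=0) if med_all else np.full(3, np.nan)
    p95 = np.median(np.array(p95_all), axis=0) if p95_all else np.full(3, np.nan)
    return UniquenessReport(
        triplet=spec,
        verdict=verdict,
        condition=region if verdict == "unique" else "none",
        median_abs_errors={"r_mm": float(med[0]), "theta_deg": float(med[1]),
                           "phi_deg": float(med[2])},
        p95_abs_errors={"r_mm": float(p95[0]), "theta_deg": float(p95[1]),
                        "phi_deg": float(p95[2])},
        overlap_count=n_overlap,
        n_records=len(sub),
        seed_verdicts=seed_verdicts,
        thresholds=thr,
    )


def uniqueness_survey(table: MappingTable, region: str = "All",
                      thresholds: UniquenessThresholds | None = None,
                      seeds=(0, 1, 2), min_records: int = 1000):
    """Run the uniqueness test for all 20 triplets on one region."""
    return [test_uniqueness(table, spec, region, thresholds, seeds,
                            min_records=min_records)
            for spec in enumerate_triplets()]
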