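"""Simulated federated-learning site construction and heterogeneity metrics.

Four partitioning strategies turn a training pool of patients into N sites:

* distribution-based class skew — per-class Dirichlet(beta) proportions;
* quantity-based class skew — each site owns a fixed number of classes;
* quantity skew — Dirichlet(beta) over site *sizes*, classes left to chance;
* source-based — sites are the true origin of the data (public vs private).

An imbalance scenario builder mixes the global class distribution with a
per-site single-class Dirac distribution, P_i = alpha * P_global +
(1 - alpha) * delta_{c_i}, so local heterogeneity is tunable from one class
per site (alpha = 0) to IID (alpha = 1).

Heterogeneity is quantified by the weighted average cosine similarity between
each site's class-count vector v_i and the global count vector V:
CS_i = v_i . V / (||v_i|| ||V||), CSbar = sum_i (n_i / n) CS_i.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .synthdata import CLASSES, PRIVATE, PUBLIC, S0, S1PLUS, PatientRecord


@dataclass(frozen=True)
class SitePartition:
    """One simulated FL site: its patients and class-count vector."""

    site_id: int
    patients: list[PatientRecord]

    @property
    def class_counts(self) -> np.ndarray:
        counts = Counter(p.binary_class for p in self.patients)
        return np.array([counts.get(c, 0) for c in CLASSES], dtype=int)

    @property
    def n_i(self) -> int:
        return len(self.patients)


@dataclass(frozen=True)
class HeterogeneityReport:
    per_site_cs: list[float]
    weighted_cs: float
    global_counts: np.ndarray
    n: int
    empty_sites: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_site_cs": [float(c) for c in self.per_site_cs],
            "weighted_cs": float(self.weighted_cs),
            "global_counts": [int(c) for c in self.global_counts],
            "n": int(self.n),
            "empty_sites": list(self.empty_sites),
        }


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Hamilton apportionment: integer counts summing to ``total``.

    Floors ``proportions * total`` then hands the remaining units to the
    largest fractional remainders, ties broken toward the lower index, so the
    result is order-stable and conserves the total exactly.
    """
    proportions = np.asarray(proportions, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    if proportions.sum() <= 0:
        raise ValueError("proportions must have positive sum")
    proportions = proportions / proportions.sum()
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = raw - counts
        # stable argsort descending; lower index wins ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def _check_partition(pool: list[PatientRecord], sites: list[SitePartition]) -> None:
    got = Counter(p.patient_id for s in sites for p in s.patients)
    want = Counter(p.patient_id for p in pool)
    if got != want:
        raise AssertionError("partition is not an exact multiset partition of the pool")


def _by_class(pool: list[PatientRecord]) -> dict[str, list[PatientRecord]]:
    out: dict[str, list[PatientRecord]] = {c: [] for c in CLASSES}
    for p in pool:
        out[p.binary_class].append(p)
    return out


def dirichlet_class_partition(
    pool: list[PatientRecord], n_sites: int, beta: float, seed: int = 0
) -> list[SitePartition]:
    """Distribution-based class skew: per-class proportions ~ Dir(beta)."""
    if not pool:
        raise ValueError("pool must be nonempty")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    members: list[list[PatientRecord]] = [[] for _ in range(n_sites)]
    for cls in CLASSES:
        patients = _by_class(pool)[cls]
        if not patients:
            continue
        patients = [patients[i] for i in rng.permutation(len(patients))]
        p = rng.dirichlet(np.full(n_sites, beta))
        counts = largest_remainder(p, len(patients))
        start = 0
        for i, c in enumerate(counts):
            members[i].extend(patients[start : start + c])
            start += c
    sites = [SitePartition(i, m) for i, m in enumerate(members)]
    _check_partition(pool, sites)
    return sites


def quantity_class_partition(
    pool: list[PatientRecord], n_sites: int, classes_per_site: int = 1
) -> list[SitePartition]:
    """Quantity-based class skew: each site owns a fixed set of classes.

    Classes are assigned round-robin (site i owns classes
    ``(i * classes_per_site + j) mod n_classes``); each class's patients are
    split equally among its owners, remainders going to the lowest site ids.
    With 2 sites and one class each, site 0 holds all S0 and site 1 all
    S1plus.
    """
    classes_present = [c for c in CLASSES if any(p.binary_class == c for p in pool)]
    owners: dict[str, list[int]] = {c: [] for c in classes_present}
    for i in range(n_sites):
        for j in range(classes_per_site):
            cls = CLASSES[(i * classes_per_site + j) % len(CLASSES)]
            if cls in owners and i not in owners[cls]:
                owners[cls].append(i)
    orphaned = [c for c, o in owners.items() if not o]
    if orphaned:
        raise ValueError(f"classes owned by zero sites: {orphaned}")
    members: list[list[PatientRecord]] = [[] for _ in range(n_sites)]
    by_class = _by_class(pool)
    for cls in classes_present:
        sites_of = sorted(owners[cls])
        counts = largest_remainder(np.full(len(sites_of), 1.0), len(by_class[cls]))
        start = 0
        for site, c in zip(sites_of, counts):
            members[site].extend(by_class[cls][start : start + c])
            start += c
    sites = [SitePartition(i, m) for i, m in enumerate(members)]
    _check_partition(pool, sites)
    return sites


def dirichlet_quantity_partition(
    pool: list[PatientRecord], n_sites: int, beta: float, seed: int = 0
) -> list[SitePartition]:
    """Quantity skew: site sizes ~ Dir(beta); class composition left to chance."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    q = rng.dirichlet(np.full(n_sites, beta))
    counts = largest_remainder(q, len(pool))
    members, start = [], 0
    for c in counts:
        members.append(shuffled[start : start + c])
        start += c
    sites = [SitePartition(i, m) for i, m in enumerate(members)]
    _check_partition(pool, sites)
    return sites


def source_partition(pool: list[PatientRecord]) -> list[SitePartition]:
    """Source-based partition: site 0 = public-like, site 1 = private-like."""
    sites = [
        SitePartition(0, [p for p in pool if p.site_of_origin == PUBLIC]),
        SitePartition(1, [p for p in pool if p.site_of_origin == PRIVATE]),
    ]
    _check_partition(pool, sites)
    return sites


def imbalance_scenario(
    pool: list[PatientRecord],
    total_patients: int = 84,
    s0_fraction: float = 0.5,
    alpha: float = 1.0,
    n_sites: int = 2,
    seed: int = 0,
    pinned_classes: list[str] | None = None,
) -> list[SitePartition]:
    """Global-imbalance / local-heterogeneity scenario builder.

    First subsamples a global set of ``total_patients`` with a largest-
    remainder split between S0 and S1plus at ``s0_fraction``; then fills each
    site (equal sizes in expectation) with a ``1 - alpha`` portion pinned to a
    single class c_i (classes cycling by site index: site 0 -> S0,
    site 1 -> S1plus, ...) and an ``alpha`` portion apportioned by the global
    class distribution. All per-site class counts use largest-remainder
    rounding and are reconciled so the global set is conserved exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 0.0 < s0_fraction < 1.0:
        raise ValueError("s0_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    class_totals = largest_remainder(np.array([s0_fraction, 1 - s0_fraction]), total_patients)
    by_class = _by_class(pool)
    chosen: dict[str, list[PatientRecord]] = {}
    for cls, need in zip(CLASSES, class_totals):
        have = by_class[cls]
        if len(have) < need:
            raise ValueError(
                f"pool has {len(have)} patients of class {cls!r}; {need} needed"
            )
        idx = rng.choice(len(have), size=int(need), replace=False)
        chosen[cls] = [have[i] for i in sorted(idx)]

    if pinned_classes is None:
        pinned_classes = [CLASSES[i % len(CLASSES)] for i in range(n_sites)]
    site_sizes = largest_remainder(np.full(n_sites, 1.0), total_patients)
    p_global = class_totals / class_totals.sum()

    # per-site class-count targets: pinned portion + IID portion
    demand = np.zeros((n_sites, len(CLASSES)), dtype=int)
    for i in range(n_sites):
        n_pin, n_iid = largest_remainder(np.array([1 - alpha, alpha]), int(site_sizes[i]))
        demand[i, CLASSES.index(pinned_classes[i])] += n_pin
        demand[i] += largest_remainder(p_global, n_iid)

    # reconcile column sums with the available class totals: move surplus
    # units to deficit classes, preferring sites with the most of the
    # surplus class (lowest site id on ties)
    for _ in range(total_patients):
        diff = demand.sum(axis=0) - class_totals
        if not diff.any():
            break
        over = int(np.argmax(diff))
        under = int(np.argmin(diff))
        site = int(np.argmax(demand[:, over]))
        demand[site, over] -= 1
        demand[site, under] += 1

    members: list[list[PatientRecord]] = [[] for _ in range(n_sites)]
    cursors = {c: 0 for c in CLASSES}
    for i in range(n_sites):
        for ci, cls in enumerate(CLASSES):
            k = int(demand[i, ci])
            members[i].extend(chosen[cls][cursors[cls] : cursors[cls] + k])
            cursors[cls] += k
    sites = [SitePartition(i, m) for i, m in enumerate(members)]
    _check_partition([p for c in CLASSES for p in chosen[c]], sites)
    return sites


def cosine_similarity_site(v_i: np.ndarray, V: np.ndarray) -> float:
    """Cosine similarity between a site's class-count vector and the global one."""
    v_i = np.asarray(v_i, dtype=float)
    V = np.asarray(V, dtype=float)
    if v_i.shape != V.shape:
        raise ValueError("class-count vectors must have the same length")
    nv, nV = np.linalg.norm(v_i), np.linalg.norm(V)
    if nv == 0 or nV == 0:
        raise ValueError("cosine similarity undefined for a zero class-count vector")
    return float(v_i @ V / (nv * nV))


def weighted_avg_cosine(sites: list[SitePartition]) -> HeterogeneityReport:
    """Size-weighted mean cosine similarity over nonempty sites."""
    nonempty = [s for s in sites if s.n_i > 0]
    if not nonempty:
        raise ValueError("all sites are empty")
    V = np.sum([s.class_counts for s in nonempty], axis=0)
    n = int(sum(s.n_i for s in nonempty))
    per_site = [cosine_similarity_site(s.class_counts, V) for s in nonempty]
    weighted = float(sum(s.n_i / n * cs for s, cs in zip(nonempty, per_site)))
    return HeterogeneityReport(
        per_site_cs=per_site,
        weighted_cs=weighted,
        global_counts=V,
        n=n,
        empty_sites=[s.site_id for s in sites if s.n_i == 0],
    )
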