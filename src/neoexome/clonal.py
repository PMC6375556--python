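"""Simplified diagnostic-to-residual clone inference and fate tracking.

Subclones within a sample are inferred by clustering variant allele fractions:
each variant contributes its (alt reads, depth) pair and the sample is
modelled as a K-component binomial mixture fit by expectation-maximisation,
with K chosen over 1..k_max by the Bayesian information criterion. This is a
deliberate simplification of whole-exome clonality tools: sites are assumed
diploid and copy-neutral, so a clone's cellular fraction is proportional to
its VAF, and no copy-number or phylogenetic modelling is attempted.

Diagnostic and residual clusters of the same patient are then matched greedily
by descending Jaccard overlap of member variant ids. A pair with overlap at or
above a threshold (0.5) is a *persistent* clone; unmatched residual clusters
are *emergent*, unmatched diagnostic clusters *extinct* — the three fates of a
subclone under the selective pressure of neoadjuvant therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .records import VariantRecord


@dataclass
class CloneCluster:
    sample_id: str
    members: list[str]  # variant uids
    mean_vaf: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CloneTrajectory:
    patient_id: str
    clone_label: str
    fate: str  # persistent | emergent | extinct
    diagnostic: CloneCluster | None
    residual: CloneCluster | None
    defining_variants: list[str]

    def __post_init__(self) -> None:
        expected = {
            "persistent": (True, True),
            "extinct": (True, False),
            "emergent": (False, True),
        }[self.fate]
        have = (self.diagnostic is not None, self.residual is not None)
        if have != expected:
            raise ValueError(f"{self.fate} trajectory with clusters {have}")


def _em_binomial(alt, depth, k: int, init_p: np.ndarray, max_iter: int = 300, tol: float = 1e-8):
    """EM for a k-component binomial mixture on (alt, depth) pairs.

    Returns (log-likelihood, component vafs, component weights, responsibilities).
    """
    n = len(alt)
    p = init_p.copy()
    pi = np.full(k, 1.0 / k)
    eps = 1e-6
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: log responsibilities
        logp = np.log(np.maximum(pi, 1e-300))[:, None] + binom.logpmf(alt[None, :], depth[None, :], p[:, None].clip(eps, 1 - eps))
        norm = logsumexp(logp, axis=0)
        resp = np.exp(logp - norm)
        ll = float(norm.sum())
        if ll - ll_old < tol:
            break
        ll_old = ll
        # M-step
        pi = resp.mean(axis=1)
        p = (resp @ alt) / np.maximum(resp @ depth, eps)
        p = p.clip(eps, 1 - eps)
    return ll, p, pi, resp


def cluster_vafs(
    records: list[VariantRecord],
    k_max: int = 5,
    seed: int = 0,
    n_jitter_restarts: int = 2,
) -> list[CloneCluster]:
    """Cluster a sample's variants into subclones by binomial-mixture EM.

    For each K in 1..k_max the mixture is fit from a fixed VAF-quantile
    initialisation grid (plus a few seeded jitter restarts) and the best K is
    chosen by BIC. Variants are assigned to their maximum-responsibility
    component; a component left with fewer than two members is dissolved into
    the nearest surviving cluster by VAF, so clusters always have size >= 2.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 variants to cluster")
    sample_id = records[0].sample_id
    alt = np.array([r.tumour_alt_reads for r in records], dtype=float)
    depth = np.array([r.tumour_depth for r in records], dtype=float)
    if (depth <= 0).any():
        raise ValueError("nonpositive depth")
    vaf = alt / depth
    rng = np.random.default_rng(seed)

    best = None  # (bic, k, p, resp)
    for k in range(1, min(k_max, len(records)) + 1):
        inits = [np.quantile(vaf, (np.arange(k) + 0.5) / k)]
        for _ in range(n_jitter_restarts if k > 1 else 0):
            inits.append(np.sort(rng.uniform(0.02, 0.98, size=k)))
        ll_best = -np.inf
        fit_best = None
        for init in inits:
            ll, p, pi, resp = _em_binomial(alt, depth, k, np.asarray(init, dtype=float))
            if ll > ll_best:
                ll_best, fit_best = ll, (p, resp)
        n_params = 2 * k - 1  # k vafs + k-1 free weights
        bic = -2.0 * ll_best + n_params * np.log(len(records))
        if best is None or bic < best[0] - 1e-9:
            best = (bic, k, *fit_best)

    _, k, p, resp = best
    assign = resp.argmax(axis=0)
    # dissolve sub-minimal components into the nearest surviving one
    while True:
        sizes = np.bincount(assign, minlength=k)
        small = [c for c in range(k) if 0 < sizes[c] < 2]
        if not small or (sizes >= 2).sum() == 0:
            break
        c = small[0]
        survivors = [j for j in range(k) if sizes[j] >= 2]
        target = min(survivors, key=lambda j: abs(p[j] - p[c]))
        assign[assign == c] = target
    clusters = []
    for c in range(k):
        idx = np.flatnonzero(assign == c)
        if idx.size == 0:
            continue
        members = [records[i].uid for i in idx]
        clusters.append(CloneCluster(sample_id, members, float(vaf[idx].mean())))
    clusters.sort(key=lambda cl: -cl.mean_vaf)
    return clusters


def _jaccard(a: set[str], b: set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def _strip_sample(uids: list[str]) -> set[str]:
    # uids embed the sample id; matching across timepoints uses the locus part
    return {u.split(":", 1)[1] for u in uids}


def track_clones(
    diagnostic: list[CloneCluster],
    residual: list[CloneCluster],
    patient_id: str = "",
    match_threshold: float = 0.5,
) -> list[CloneTrajectory]:
    """Match clusters across timepoints and classify each clone's fate.

    Pairs are taken greedily by descending Jaccard overlap of member variant
    loci; each cluster is used at most once, pairs below the threshold are not
    matched. Matched pairs are persistent, leftover residual clusters emergent,
    leftover diagnostic clusters extinct.
    """
    for clusters in (diagnostic, residual):
        seen: set[str] = set()
        for cl in clusters:
            mem = set(cl.members)
            if mem & seen:
                raise ValueError("clusters within one sample share a variant")
            seen |= mem

    d_loci = [_strip_sample(cl.members) for cl in diagnostic]
    r_loci = [_strip_sample(cl.members) for cl in residual]
    pairs = sorted(
        (
            (_jaccard(d_loci[i], r_loci[j]), i, j)
            for i in range(len(diagnostic))
            for j in range(len(residual))
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_d: set[int] = set()
    used_r: set[int] = set()
    trajectories: list[CloneTrajectory] = []
    label = 0
    for jac, i, j in pairs:
        if jac < match_threshold:
            break
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        label += 1
        shared = sorted(d_loci[i] & r_loci[j])
        trajectories.append(
            CloneTrajectory(patient_id, f"clone_{label}", "persistent", diagnostic[i], residual[j], shared)
        )
    for i, cl in enumerate(diagnostic):
        if i not in used_d:
            label += 1
            trajectories.append(
                CloneTrajectory(patient_id, f"clone_{label}", "extinct", cl, None, sorted(d_loci[i]))
            )
    for j, cl in enumerate(residual):
        if j not in used_r:
            label += 1
            trajectories.append(
                CloneTrajectory(patient_id, f"clone_{label}", "emergent", None, cl, sorted(r_loci[j]))
            )
    return trajectories


def river_table(trajectories: list[CloneTrajectory]) -> pd.DataFrame:
    """Plot-ready long table: one row per (clone, timepoint) with its fraction."""
    rows = []
    for tr in trajectories:
        for timepoint, cluster in (("diagnostic", tr.diagnostic), ("residual", tr.residual)):
            if cluster is None:
                continue
            rows.append(
                {
                    "patient_id": tr.patient_id,
                    "clone": tr.clone_label,
                    "fate": tr.fate,
                    "timepoint": timepoint,
                    "fraction": cluster.mean_vaf,
                    "n_variants": cluster.size,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "clone", "fate", "timepoint", "fraction", "n_variants"])
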