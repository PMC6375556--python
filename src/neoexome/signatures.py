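"""96-context mutation catalogs and reference-signature refitting.

A sample's catalog of single-base substitutions, classed into the canonical 96
trinucleotide categories, is refit against a reference signature matrix (rows
are signatures, each a probability distribution over the 96 classes) by
iterative forward selection: repeatedly pick the single signature whose
weight, optimised by golden-section line search with all other weights held
fixed, most reduces the squared reconstruction error; stop when the
improvement falls below a tolerance; then prune signatures contributing less
than a minimum fraction (0.06 by default) and re-optimise the survivors. This
mirrors the behaviour of iterative refitting tools built on the same idea
while remaining a fresh implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import CLASS_INDEX, SBS96_CLASSES, sbs96_class
from .io_formats import SignatureMatrix
from .records import SNV, VariantRecord


@dataclass
class MutationCatalog:
    """Counts of a sample's SNVs over the 96 canonical classes."""

    sample_id: str
    counts: np.ndarray  # shape (96,), nonnegative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have 96 classes")
        if (self.counts < 0).any():
            raise ValueError("negative catalog counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty catalog")
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context_class": SBS96_CLASSES, "count": self.counts.astype(int)})


# Inclusion rule for signature analysis: strict inequalities on VAF and quality.
CATALOG_MIN_VAF = 0.10
CATALOG_MIN_QUALITY = 20.0


def build_catalog(
    records: list[VariantRecord],
    sample_id: str | None = None,
    min_vaf: float = CATALOG_MIN_VAF,
    min_quality: float = CATALOG_MIN_QUALITY,
) -> MutationCatalog:
    """Count qualifying SNVs (VAF > 10%, quality > 20) into the 96 classes.

    All consequence classes contribute — synonymous, intronic and intergenic
    calls included. Non-SNVs are ignored; a qualifying SNV without a context
    raises.
    """
    counts = np.zeros(96)
    sid = sample_id
    for rec in records:
        if rec.kind != SNV:
            continue
        if not (rec.vaf > min_vaf and rec.call_quality > min_quality):
            continue
        if not rec.context:
            raise ValueError(f"SNV {rec.uid} lacks a trinucleotide context")
        counts[CLASS_INDEX[sbs96_class(rec.ref, rec.alt, rec.context)]] += 1
        if sid is None:
            sid = rec.sample_id
    return MutationCatalog(sample_id=sid or "", counts=counts)


@dataclass
class SignatureFit:
    """Nonnegative signature weights for one catalog, pruned at a minimum contribution.

    `unexplained` is the mixture mass not attributed to any reference
    signature, so the reported weights plus `unexplained` sum to one.
    """

    sample_id: str
    weights: dict[str, float]
    unexplained: float
    sse: float
    n_mutations: float
    min_contribution: float = 0.06
    reconstruction: np.ndarray | None = field(default=None, repr=False)

    def weight_vector(self, signature_ids: list[str]) -> np.ndarray:
        return np.array([self.weights.get(s, 0.0) for s in signature_ids])


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Minimiser of a unimodal f on [lo, hi] by golden-section search."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _sse(target: np.ndarray, S: np.ndarray, w: np.ndarray) -> float:
    resid = target - w @ S
    return float(resid @ resid)


def _coordinate_refit(target: np.ndarray, S: np.ndarray, w: np.ndarray, tol: float) -> np.ndarray:
    """Cyclic per-signature golden-section descent until the SSE improvement < tol."""
    w = w.copy()
    err = _sse(target, S, w)
    while True:
        for j in range(len(w)):
            others = w @ S - w[j] * S[j]
            resid = target - others

            def f(x, row=S[j], resid=resid):
                d = resid - x * row
                return float(d @ d)

            w[j] = _golden_section(f, 0.0, 1.0)
        new_err = _sse(target, S, w)
        if err - new_err < tol * max(err, 1e-9):
            break
        err = new_err
    return w


def fit_signatures(
    catalog: MutationCatalog,
    matrix: SignatureMatrix,
    min_contribution: float = 0.06,
    tol: float = 1e-3,
) -> SignatureFit:
    """Refit a catalog as a nonnegative mixture of reference signatures.

    Forward selection starting from the empty mixture: at each round every
    signature's weight is line-searched on [0, 1] with the rest fixed, the
    single best SSE reduction is committed, and the active set is re-optimised
    by cyclic coordinate descent; rounds stop when the best improvement falls
    below `tol` relative to the current SSE (so the stop rule tracks the
    attainable optimum). Weights under `min_contribution` are then pruned and the
    survivors re-optimised (repeated until stable). Deterministic given its
    inputs. No trinucleotide-opportunity rescaling is applied: the raw catalog
    proportions are fit directly (an opportunity-weights hook can be layered on
    the matrix by the caller).
    """
    if catalog.total < 1:
        raise ValueError("cannot fit an empty catalog")
    S = matrix.values  # (n_sigs, 96)
    ids = matrix.signature_ids
    if S.shape[1] != 96:
        raise ValueError("signature matrix must have 96 context columns")
    target = catalog.proportions()

    n = S.shape[0]
    w = np.zeros(n)
    err = _sse(target, S, w)
    while True:
        best_j, best_wj, best_err = -1, 0.0, err
        for j in range(n):
            others = w @ S - w[j] * S[j]
            resid = target - others

            def f(x, row=S[j], resid=resid):
                d = resid - x * row
                return float(d @ d)

            xj = _golden_section(f, 0.0, 1.0)
            ej = f(xj)
            if ej < best_err - 1e-15:
                best_j, best_wj, best_err = j, xj, ej
        if best_j < 0 or err - best_err < tol * max(err, 1e-9):
            break
        w[best_j] = best_wj
        w = _coordinate_refit(target, S, w, tol / 10.0)
        err = _sse(target, S, w)

    def _prune(w: np.ndarray) -> np.ndarray:
        # prune-and-refit until every surviving weight clears the floor
        while (w > 0).any() and (w[w > 0] < min_contribution).any():
            keep = w >= min_contribution
            if not keep.any():
                return np.zeros(n)
            idx = np.flatnonzero(keep)
            w_sub = _coordinate_refit(target, S[idx], w[idx], tol / 10.0)
            w = np.zeros(n)
            w[idx] = w_sub
        return w

    w = _prune(w)
    total = float(w.sum())
    if total > 1.0:
        # rescaling onto the simplex can nudge a boundary weight under the
        # floor, so prune once more afterwards
        w = _prune(w / total)
        total = min(float(w.sum()), 1.0)
    weights = {ids[i]: float(w[i]) for i in np.flatnonzero(w > 0)}
    return SignatureFit(
        sample_id=catalog.sample_id,
        weights=weights,
        unexplained=max(0.0, 1.0 - total),
        sse=_sse(target, S, w),
        n_mutations=catalog.total,
        min_contribution=min_contribution,
        reconstruction=w @ S,
    )
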