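"""96-channel mutation catalogs and reference-signature refitting.

A tumor's retained single-nucleotide substitutions are histogrammed over the 96
trinucleotide channels; the normalized catalog is then approximated by a
non-negative combination of reference signatures by iterative forward
selection / coordinate refinement of a sum-of-squares reconstruction objective:
starting from the empty solution, each step moves the single signature weight
(within the simplex constraint sum <= 1) that most reduces the squared error,
stopping when the improvement falls below ``tol``. Weights below the reporting
cutoff are then zeroed and the surviving signatures re-optimized. The
unexplained fraction 1 - sum(weights) is reported as the residual.

The refitter is exposed statsmodels-style: ``SignatureRefit(catalog, ref).fit()``
returns a :class:`SignatureRefitResults` with the exposures, the reconstruction
error and a ``summary()`` table; :func:`refit_exposures` is the functional
shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .channels import CHANNEL_INDEX, channel_of
from .types import ExposureVector, MutationCatalog, SignatureMatrix, SomaticVariant

#: Signatures whose combined weight summarizes MMR-deficiency exposure.
MMR_SIGNATURES = ("6", "20", "26")
#: Group-average weights below this are pooled into the "Other" display bucket.
OTHER_BUCKET_CUTOFF = 0.05


def build_catalog(variants: Iterable[SomaticVariant], sample_id: str) -> MutationCatalog:
    """Channel histogram over a sample's single-nucleotide substitutions.

    Indels contribute nothing. Every SNV must carry its 3-mer context; the
    offending variant is named otherwise.
    """
    counts = np.zeros(96, dtype=int)
    for v in variants:
        if v.sample_id != sample_id or not v.is_snv:
            continue
        if v.context3 is None:
            raise ValueError(
                f"SNV lacking context3: {v.sample_id} {v.chrom}:{v.pos} "
                f"{v.ref_allele}>{v.alt_allele}"
            )
        counts[CHANNEL_INDEX[channel_of(v.ref_allele, v.alt_allele, v.context3)]] += 1
    return MutationCatalog(sample_id=sample_id, counts=counts)


def _coordinate_pass(
    t: np.ndarray,
    S: np.ndarray,
    w: np.ndarray,
    support: np.ndarray,
    tol: float,
    max_iter: int,
) -> int:
    """Greedy single-coordinate refinement of ``w`` in place; returns iterations used.

    ``tol`` is the minimum improvement of the L2 reconstruction error
    ||t - w S|| that justifies another step.
    """
    norms = np.einsum("ij,ij->i", S, S)
    recon = w @ S
    err = float(np.sqrt(((t - recon) ** 2).sum()))
    for it in range(max_iter):
        r = t - recon
        best_j = -1
        best_gain = 0.0
        best_wj = 0.0
        for j in support:
            rs = r @ S[j]
            rj_dot = rs + w[j] * norms[j]
            wj_new = min(max(rj_dot / norms[j], 0.0), 1.0)
            d = wj_new - w[j]
            if d == 0.0:
                continue
            gain = 2 * d * rs - d * d * norms[j]  # SSE reduction, always >= 0
            if gain > best_gain:
                best_gain = gain
                best_j = j
                best_wj = wj_new
        if best_j < 0:
            return it
        new_err = float(np.sqrt(max(err * err - best_gain, 0.0)))
        if err - new_err < tol:
            return it
        recon = recon + (best_wj - w[best_j]) * S[best_j]
        w[best_j] = best_wj
        err = new_err
    return max_iter


def _constrained_nnls(t: np.ndarray, S_sub: np.ndarray, penalty: float = 1e4) -> np.ndarray:
    """Least-squares weights >= 0 with sum <= 1 on a fixed signature support.

    The simplex bound is imposed through a slack variable and a heavily
    penalized row ``sum(w) + slack = 1``, turning the problem into plain NNLS.
    """
    from scipy.optimize import nnls

    k = S_sub.shape[0]
    A = np.zeros((97, k + 1))
    A[:96, :k] = S_sub.T
    A[96, :] = penalty
    b = np.concatenate([t, [penalty]])
    sol, _ = nnls(A, b)
    return sol[:k]


class SignatureRefit:
    """Model object: one catalog against a reference signature matrix."""

    def __init__(
        self,
        catalog: MutationCatalog,
        reference: SignatureMatrix,
        opportunity: Optional[np.ndarray] = None,
    ) -> None:
        if catalog.total == 0:
            raise ValueError(f"empty catalog for sample {catalog.sample_id}")
        self.catalog = catalog
        self.reference = reference
        #: optional per-channel opportunity weights (e.g. panel trinucleotide
        #: abundance); both the catalog and the signatures are divided by it.
        self.opportunity = None if opportunity is None else np.asarray(opportunity, dtype=float)

    def _prepare(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.catalog.fractions()
        S = self.reference.probs.copy()
        if self.opportunity is not None:
            if self.opportunity.shape != (96,) or (self.opportunity <= 0).any():
                raise ValueError("opportunity must be 96 positive weights")
            t = t / self.opportunity
            t = t / t.sum()
            S = S / self.opportunity
            S = S / S.sum(axis=1, keepdims=True)
        return t, S

    def fit(
        self,
        cutoff: float = 0.06,
        tol: float = 1e-3,
        max_iter: int = 1000,
    ) -> "SignatureRefitResults":
        t, S = self._prepare()
        n_sig = len(self.reference.signature_ids)
        w = np.zeros(n_sig)
        all_sigs = np.arange(n_sig)
        n_iter = _coordinate_pass(t, S, w, all_sigs, tol, max_iter)
        # selection runs with per-weight bounds only; enforce the simplex here
        total = w.sum()
        if total > 1.0:
            w /= total
        # reporting cutoff, then re-optimize the surviving support exactly
        w[w < cutoff] = 0.0
        survivors = np.nonzero(w)[0]
        if survivors.size:
            w[survivors] = _constrained_nnls(t, S[survivors])
            w[w < 1e-12] = 0.0
        sse = float(((t - w @ S) ** 2).sum())
        weights = {
            sig: float(w[i]) for i, sig in enumerate(self.reference.signature_ids) if w[i] > 0
        }
        return SignatureRefitResults(
            model=self,
            exposures=ExposureVector(weights=weights),
            sse=sse,
            n_iter=n_iter,
            cutoff=cutoff,
            tol=tol,
        )


@dataclass
class SignatureRefitResults:
    model: SignatureRefit
    exposures: ExposureVector
    sse: float
    n_iter: int
    cutoff: float
    tol: float

    @property
    def residual(self) -> float:
        return self.exposures.residual

    def reconstruction(self) -> np.ndarray:
        t, S = self.model._prepare()
        w = np.array(
            [self.exposures.get(s) for s in self.model.reference.signature_ids]
        )
        return w @ S

    def summary(self) -> str:
        lines = [
            f"Signature refit: sample {self.model.catalog.sample_id} "
            f"({self.model.catalog.total} substitutions)",
            f"SSE {self.sse:.3e} | residual {self.residual:.3f} | "
            f"cutoff {self.cutoff} | tol {self.tol}",
            "signature  weight",
        ]
        for sig, wt in sorted(self.exposures.weights.items(), key=lambda kv: -kv[1]):
            lines.append(f"{sig:>9}  {wt:.3f}")
        return "\n".join(lines)


def refit_exposures(
    catalog: MutationCatalog,
    reference: SignatureMatrix,
    cutoff: float = 0.06,
    tol: float = 1e-3,
) -> ExposureVector:
    """Functional shortcut around :class:`SignatureRefit`."""
    return SignatureRefit(catalog, reference).fit(cutoff=cutoff, tol=tol).exposures


@dataclass(frozen=True)
class GroupSignatureSummary:
    group: str
    mean_weight: Mapping[str, float]
    combined_mmr: float
    other_bucket: float


def group_signature_summary(
    exposures: Mapping[str, ExposureVector],
    groups: Mapping[str, str],
    mmr_signatures: Sequence[str] = MMR_SIGNATURES,
    other_cutoff: float = OTHER_BUCKET_CUTOFF,
    min_catalog_total: int = 0,
    catalog_totals: Optional[Mapping[str, int]] = None,
) -> list[GroupSignatureSummary]:
    """Unweighted per-group means of per-sample signature weights.

    ``combined_mmr`` sums the group means of the MMR-deficiency signatures
    (6, 20 and 26 by default); ``other_bucket`` pools all mean weights below
    ``other_cutoff``. Samples with catalogs smaller than ``min_catalog_total``
    can optionally be excluded (requires ``catalog_totals``).
    """
    by_group: dict[str, list[ExposureVector]] = {}
    for sample_id, exp in exposures.items():
        if min_catalog_total and catalog_totals is not None:
            if catalog_totals.get(sample_id, 0) < min_catalog_total:
                continue
        group = str(groups[sample_id])
        by_group.setdefault(group, []).append(exp)
    if any(not members for members in by_group.values()) or not by_group:
        raise ValueError("every group must contain at least one sample")
    out = []
    for group, members in by_group.items():
        sig_ids = sorted({s for e in members for s in e.weights}, key=_sig_key)
        means = {
            sig: sum(e.get(sig) for e in members) / len(members) for sig in sig_ids
        }
        combined = sum(means.get(str(s), 0.0) for s in mmr_signatures)
        other = sum(w for w in means.values() if w < other_cutoff)
        out.append(
            GroupSignatureSummary(
                group=group, mean_weight=means, combined_mmr=combined, other_bucket=other
            )
        )
    return out


def _sig_key(sig: str):
    return (0, int(sig)) if sig.isdigit() else (1, sig)


def group_pooled_exposures(
    catalogs: Mapping[str, MutationCatalog],
    groups: Mapping[str, str],
    reference: SignatureMatrix,
    cutoff: float = 0.06,
    tol: float = 1e-3,
) -> dict[str, ExposureVector]:
    """Collective per-group exposures: refit the summed group catalog.

    Pooling the catalogs of a group before refitting is the collective-calling
    route; it is far better conditioned than averaging per-sample refits when
    many tumors carry few mutations, at the price of weighting tumors by their
    mutation counts.
    """
    pooled: dict[str, np.ndarray] = {}
    for sample_id, cat in catalogs.items():
        group = str(groups[sample_id])
        pooled.setdefault(group, np.zeros(96, dtype=int))
        pooled[group] = pooled[group] + cat.counts
    return {
        group: refit_exposures(
            MutationCatalog(sample_id=f"pooled:{group}", counts=counts),
            reference,
            cutoff=cutoff,
            tol=tol,
        )
        for group, counts in pooled.items()
    }
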