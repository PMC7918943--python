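"""Constrained signature fitting with bootstrap presence calls.

Exposures are estimated by non-negative least squares of the 96-channel
count vector on the reference-signature matrix, followed by iterative
sparsity pruning: any signature attracting less than ``prune_threshold``
(default 5%) of the fitted mutations is dropped and the fit re-solved until
stable.  Pruning guards against the over-fitting of inappropriate
signatures that plagues fitting in low-burden samples.

Presence of a signature is called with a nonparametric bootstrap: each
replicate resamples the catalogue multinomially from its empirical channel
frequencies, refits, and records whether the signature's exposure fraction
reaches the exposure threshold (default 5% of the sample's mutations).  The
empirical probability over replicates, compared against a presence cutoff
(default 0.9), gives the presence call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io_formats import SignatureSet
from .mutation_catalogue import MutationalCatalogue

DEFAULT_PRUNE_THRESHOLD = 0.05
DEFAULT_EXPOSURE_THRESHOLD = 0.05
DEFAULT_N_BOOT = 200
DEFAULT_PRESENCE_CUTOFF = 0.9


@dataclass
class SignatureFit:
    sample_id: str
    exposures: dict  # signature -> fitted mutation count (non-negative real)
    exposure_fractions: dict  # signature -> fraction of fitted mutations
    reconstruction: np.ndarray  # 96-vector
    cosine_to_reconstruction: float
    bootstrap_presence: dict = field(default_factory=dict)

    def fraction(self, name: str) -> float:
        return self.exposure_fractions.get(name, 0.0)


def cosine_similarity(a, b) -> float:
    """Standard cosine similarity; symmetric and scale-invariant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _nnls_exposures(matrix: np.ndarray, counts: np.ndarray) -> np.ndarray:
    solution, _ = nnls(matrix, counts)
    return solution


def fit_exposures(
    catalogue: MutationalCatalogue,
    signature_set: SignatureSet,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
) -> SignatureFit:
    """NNLS fit of the catalogue on the signature matrix with iterative
    pruning of signatures below ``prune_threshold`` exposure fraction."""
    if catalogue.total == 0:
        raise ValueError("cannot fit an empty catalogue")
    counts = catalogue.counts.astype(float)
    matrix = np.asarray(signature_set.matrix, dtype=float)
    names = list(signature_set.names)

    active = list(range(len(names)))
    while True:
        exposures = _nnls_exposures(matrix[:, active], counts)
        total_fit = exposures.sum()
        if total_fit == 0:
            break
        fractions = exposures / total_fit
        keep = [i for i, f in zip(active, fractions) if f >= prune_threshold]
        if not keep:  # degenerate: retain the single largest contributor
            keep = [active[int(np.argmax(fractions))]]
        if keep == active:
            break
        active = keep

    exp_map = {names[i]: 0.0 for i in range(len(names))}
    frac_map = {names[i]: 0.0 for i in range(len(names))}
    total_fit = exposures.sum()
    for i, e in zip(active, exposures):
        exp_map[names[i]] = float(e)
        frac_map[names[i]] = float(e / total_fit) if total_fit else 0.0
    reconstruction = matrix[:, active] @ exposures
    cos = (
        cosine_similarity(counts, reconstruction)
        if reconstruction.any()
        else 0.0
    )
    return SignatureFit(
        sample_id=catalogue.sample_id,
        exposures=exp_map,
        exposure_fractions=frac_map,
        reconstruction=reconstruction,
        cosine_to_reconstruction=cos,
    )


def bootstrap_presence(
    catalogue: MutationalCatalogue,
    signature_set: SignatureSet,
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
) -> dict:
    """Empirical probability, per signature, that its exposure fraction is
    >= ``threshold`` under multinomial resampling of the catalogue."""
    if catalogue.total == 0:
        raise ValueError("cannot bootstrap an empty catalogue")
    rng = np.random.default_rng(seed)
    freqs = catalogue.frequencies()
    hits = {name: 0 for name in signature_set.names}
    for _ in range(n_boot):
        resampled = rng.multinomial(catalogue.total, freqs)
        boot_cat = MutationalCatalogue(catalogue.sample_id, resampled)
        fit = fit_exposures(boot_cat, signature_set, prune_threshold=prune_threshold)
        for name in signature_set.names:
            if fit.fraction(name) >= threshold:
                hits[name] += 1
    return {name: hits[name] / n_boot for name in signature_set.names}


def fit_with_bootstrap(
    catalogue: MutationalCatalogue,
    signature_set: SignatureSet,
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
) -> SignatureFit:
    fit = fit_exposures(catalogue, signature_set, prune_threshold=prune_threshold)
    fit.bootstrap_presence = bootstrap_presence(
        catalogue,
        signature_set,
        threshold=threshold,
        n_boot=n_boot,
        seed=seed,
        prune_threshold=prune_threshold,
    )
    return fit


@dataclass(frozen=True)
class UvVerdict:
    verdict: str  # "UV-consistent" or "no UV evidence"
    uv_signature_present: bool
    cc_tt_doublets_present: bool
    strand_bias_supporting: bool
    uv_presence_probability: float


def uv_presence_report(
    fit: SignatureFit,
    doublet_stats: tuple,
    strand_bias_table,
    uv_signature: str = "uv",
    presence_cutoff: float = DEFAULT_PRESENCE_CUTOFF,
    strand_bias_alpha: float = 0.05,
) -> UvVerdict:
    """Combine signature, doublet and strand-bias evidence into a UV verdict.

    "UV-consistent" requires both a confident UV signature (bootstrap
    presence probability >= cutoff) and CC>TT doublets; transcriptional
    strand bias in C>T is reported as supporting evidence only.
    """
    if not fit.bootstrap_presence:
        raise ValueError("fit carries no bootstrap presence probabilities")
    prob = fit.bootstrap_presence.get(uv_signature, 0.0)
    uv_present = prob >= presence_cutoff
    _, cc_tt = doublet_stats
    doublets_present = cc_tt > 0
    bias_p = strand_bias_table.p_values.get("C>T", 1.0)
    bias_supporting = bias_p < strand_bias_alpha
    verdict = (
        "UV-consistent" if (uv_present and doublets_present) else "no UV evidence"
    )
    return UvVerdict(
        verdict=verdict,
        uv_signature_present=uv_present,
        cc_tt_doublets_present=doublets_present,
        strand_bias_supporting=bias_supporting,
        uv_presence_probability=prob,
    )
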