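"""Synthetic data generators for a half-diallel experiment.

Three generators cover the inputs of the full analysis pipeline:

* :func:`simulate_diallel` — plot-level phenotypes for an RCBD half diallel
  under the additive/non-additive model
  ``y_ijk = mu + b_k + g_i + g_j + s_ij + e_ijk`` (selfs carry ``2 g_i``),
  with known variance components so that estimator recovery can be tested.
* :func:`simulate_parent_snps` — a biallelic SNP matrix for the parents with
  controllable pairwise divergence, feeding the identity-by-state distances.
* :func:`simulate_colour_kinetics` — paired CIELAB readings at 0 and 10 min
  after cutting, feeding the browning-trait derivations.

All generators take an explicit seed and are deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .design import DiallelDesign

PLOT_COLUMNS = ["block", "parent_a", "parent_b", "trait", "value"]


@dataclass
class TruthParams:
    """True generative parameters for one trait of a simulated diallel.

    ``sigma2_g`` / ``sigma2_s`` are the variances of the i.i.d. normal draws
    behind the true GCA vector ``g`` (centred to sum exactly to zero) and the
    symmetric SCA matrix ``s`` (left uncentred: Griffing's estimates are only
    defined up to the model's identifiability constraints, so recovery is
    judged against the least-squares projection of the truth, not the raw
    draws).  ``sigma2_block`` and ``sigma2_e`` are the block and plot residual
    variances.
    """

    mu: float = 0.0
    sigma2_g: float = 1.0
    sigma2_s: float = 0.5
    sigma2_block: float = 0.1
    sigma2_e: float = 0.5
    g: np.ndarray | None = None
    s: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_s", "sigma2_block", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def realize(self, p: int, rng: np.random.Generator) -> "TruthParams":
        """Draw true effect vectors for ``p`` parents where not given."""
        g = self.g
        if g is None:
            g = rng.normal(0.0, math.sqrt(self.sigma2_g), size=p)
            g = g - g.mean()  # exact sum-to-zero
        else:
            g = np.asarray(g, dtype=float)
            if g.shape != (p,):
                raise ValueError(f"g must have shape ({p},)")
        s = self.s
        if s is None:
            draws = rng.normal(0.0, math.sqrt(self.sigma2_s), size=(p, p))
            s = np.triu(draws)
            s = s + np.triu(s, 1).T
        else:
            s = np.asarray(s, dtype=float)
            if s.shape != (p, p) or not np.allclose(s, s.T):
                raise ValueError(f"s must be a symmetric ({p},{p}) matrix")
        return TruthParams(
            mu=self.mu,
            sigma2_g=self.sigma2_g,
            sigma2_s=self.sigma2_s,
            sigma2_block=self.sigma2_block,
            sigma2_e=self.sigma2_e,
            g=g,
            s=s,
            seed=self.seed,
        )


def simulate_diallel(
    design: DiallelDesign,
    params: TruthParams,
    trait: str = "trait",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a plot-level RCBD phenotype table for one trait.

    Each plot value is ``mu + b_k + g_i + g_j + s_ij + e_ijk``; the self entry
    {i,i} is generated as ``mu + b_k + 2 g_i + s_ii + e_iik``.  Block effects
    ``b_k ~ N(0, sigma2_block)`` and residuals ``e ~ N(0, sigma2_e)``.

    Returns a tidy table with columns ``block, parent_a, parent_b, trait,
    value`` containing ``b * p(p+1)/2`` rows.  The same seed yields a
    byte-identical table.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    realized = params.realize(design.p, rng)
    g, s = realized.g, realized.s

    block_eff = rng.normal(0.0, math.sqrt(params.sigma2_block), size=design.blocks)
    entries = design.entries
    rows = []
    for k in range(design.blocks):
        noise = rng.normal(0.0, math.sqrt(params.sigma2_e), size=len(entries))
        for (a, b), e in zip(entries, noise):
            i, j = design.index_of(a), design.index_of(b)
            y = params.mu + block_eff[k] + g[i] + g[j] + s[i, j] + e
            rows.append((k + 1, a, b, trait, y))
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)


def _pair_divergence(eps: np.ndarray) -> np.ndarray:
    """Expected pairwise call mismatch under per-parent flip rates."""
    e = eps[:, None]
    f = eps[None, :]
    return e + f - 2.0 * e * f


def _solve_flip_rates(target: np.ndarray) -> np.ndarray:
    """Per-parent flip rates whose pairwise mismatch matches ``target``.

    The generative model assigns each marker an ancestral allele and flips it
    independently per parent with rate ``eps_a``; two parents then disagree at
    a marker with probability ``eps_a + eps_b - 2 eps_a eps_b``.  Rates are
    fitted by bounded least squares; a scalar target has the closed form
    ``eps = (1 - sqrt(1 - 2 d)) / 2`` (attainable only for d <= 0.5 when all
    pairs must diverge equally).
    """
    p = target.shape[0]
    off = target[np.triu_indices(p, 1)]
    if np.allclose(off, off[0] if off.size else 0.0):
        d = float(off[0]) if off.size else 0.0
        if d > 0.5:
            raise ValueError(
                "a uniform pairwise divergence above 0.5 is not attainable "
                "under a biallelic ancestral-flip model"
            )
        eps = (1.0 - math.sqrt(1.0 - 2.0 * d)) / 2.0
        return np.full(p, eps)

    iu = np.triu_indices(p, 1)

    def resid(eps):
        return _pair_divergence(eps)[iu] - target[iu]

    x0 = np.full(p, min(0.25, max(1e-3, float(off.mean()) / 2)))
    sol = least_squares(resid, x0, bounds=(0.0, 1.0))
    return sol.x


def simulate_parent_snps(
    parent_ids,
    n_markers: int,
    divergence,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a biallelic SNP matrix (markers x parents) with target divergence.

    Calls count copies of the alternate allele (0/1/2); missing calls are NaN.
    ``divergence`` is a scalar or a symmetric p x p matrix of target pairwise
    genetic distances GD = 1 - IBS; the expected GD between two simulated
    parents approaches the target as ``n_markers`` grows.  The default model
    produces homozygous calls (0/2), for which GD equals the call mismatch
    probability.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    parent_ids = [str(x) for x in parent_ids]
    p = len(parent_ids)

    if np.isscalar(divergence):
        target = np.full((p, p), float(divergence))
        np.fill_diagonal(target, 0.0)
    else:
        target = np.asarray(divergence, dtype=float)
        if target.shape != (p, p) or not np.allclose(target, target.T):
            raise ValueError("divergence must be a scalar or symmetric p x p matrix")
    if target.min() < 0 or target.max() > 1:
        raise ValueError("divergence entries must lie in [0, 1]")

    eps = _solve_flip_rates(target)
    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 2, size=n_markers)
    calls = np.empty((n_markers, p), dtype=float)
    for a in range(p):
        flips = rng.random(n_markers) < eps[a]
        allele = np.where(flips, 1 - ancestral, ancestral)
        calls[:, a] = 2.0 * allele
    if missing_rate > 0:
        mask = rng.random((n_markers, p)) < missing_rate
        calls[mask] = np.nan
    index = [f"M{m + 1:06d}" for m in range(n_markers)]
    return pd.DataFrame(calls, index=index, columns=parent_ids)


def simulate_colour_kinetics(
    design: DiallelDesign,
    drift: dict | tuple = (-3.0, 0.5, 1.0),
    noise_sd: float = 0.5,
    baseline: tuple = (81.0, -2.3, 17.4),
    baseline_sd: tuple = (4.0, 1.2, 4.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate paired 0-min / 10-min CIELAB flesh-colour readings.

    Each genotype entry receives a latent baseline colour (L*, a*, b*) and a
    browning drift applied over the 10 minutes after cutting; block-level
    readings add measurement noise.  ``drift`` is either one (dL, da, db)
    triple for all entries or a mapping ``{(parent_a, parent_b): triple}``.
    L* values are clipped to the CIELAB range [0, 100].  Defaults emulate pale
    eggplant flesh that darkens after cutting.
    """
    rng = np.random.default_rng(seed)
    entries = design.entries
    rows = []
    for a, b in entries:
        base = np.array(baseline) + rng.normal(0.0, baseline_sd, size=3)
        base[0] = np.clip(base[0], 0.0, 100.0)
        if isinstance(drift, dict):
            d = np.asarray(drift[(a, b)], dtype=float)
        else:
            d = np.asarray(drift, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("drift magnitudes must be finite")
        for k in range(design.blocks):
            r0 = base + rng.normal(0.0, noise_sd, size=3)
            r10 = r0 + d + rng.normal(0.0, noise_sd, size=3)
            r0[0] = np.clip(r0[0], 0.0, 100.0)
            r10[0] = np.clip(r10[0], 0.0, 100.0)
            rows.append((a, b, k + 1, *r0, *r10))
    return pd.DataFrame(
        rows,
        columns=[
            "parent_a", "parent_b", "block",
            "L0", "a0", "b0", "L10", "a10", "b10",
        ],
    )
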