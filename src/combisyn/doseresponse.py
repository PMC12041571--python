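"""Assay geometry, Hill responses and reference-model synergy surfaces.

The screen tests each pair on a 10x10 matrix: dose index 0 is the vehicle
(zero dose) and indices 1..9 form nine 1:2 serial dilutions placed so the
compound's IC50 falls mid-range.  Responses are fractional inhibition in
[0, 1] (0 = vehicle control, 1 = "no cells" positive control).  Synergy is
quantified as the observed response minus a non-interaction reference
surface (HSA or Bliss independence) built from the single-agent margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Compound, CombinationKey, make_key

#: Scale linking simulated excess-Bliss inhibition to (1 - gamma).
DEFAULT_KAPPA = 0.25


def concentration_grid(log_ic50: float, n_points: int = 10, dilution: float = 2.0) -> np.ndarray:
    """Dose vector: element 0 is zero dose, elements 1..n-1 a geometric series.

    The series is placed so the IC50 sits between elements 5 and 6 (their
    geometric mean), i.e. roughly mid-range of the nine nonzero doses.
    """
    if not math.isfinite(log_ic50):
        raise ValueError("log_ic50 must be finite")
    if dilution <= 1:
        raise ValueError(f"dilution must exceed 1, got {dilution}")
    ic50 = 10.0 ** log_ic50
    k = np.arange(1, n_points)
    mid = (n_points + 1) / 2.0  # 5.5 for the 10-point grid
    conc = np.concatenate(([0.0], ic50 * dilution ** (k - mid)))
    return conc


def hill_response(conc, ic50: float, slope: float = 1.0, e_max: float = 1.0):
    """Fractional inhibition ``e_max * c^h / (c^h + ic50^h)``; 0 at zero dose."""
    if ic50 <= 0 or slope <= 0 or not (0 < e_max <= 1):
        raise ValueError("require ic50 > 0, slope > 0, 0 < e_max <= 1")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = (conc / ic50) ** slope
    resp = e_max * ratio / (1.0 + ratio)
    return resp if resp.ndim else float(resp)


def _check_fraction(x, name):
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def bliss_expected(s_a, s_b):
    """Bliss independence: s_a + s_b - s_a*s_b (probabilistic union)."""
    a = _check_fraction(s_a, "s_a")
    b = _check_fraction(s_b, "s_b")
    out = a + b - a * b
    return out if out.ndim else float(out)


def hsa_expected(s_a, s_b):
    """Highest single agent: max(s_a, s_b)."""
    a = _check_fraction(s_a, "s_a")
    b = _check_fraction(s_b, "s_b")
    out = np.maximum(a, b)
    return out if out.ndim else float(out)


_REFERENCE_MODELS = {"bliss": bliss_expected, "hsa": hsa_expected}


@dataclass(frozen=True)
class DoseResponseMatrix:
    """10x10 combination response block (row index = conc_a, col index = conc_b)."""

    key: CombinationKey
    conc_a: np.ndarray
    conc_b: np.ndarray
    response: np.ndarray
    replicate: int = 1

    def __post_init__(self):
        resp = np.asarray(self.response, dtype=float)
        ca = np.asarray(self.conc_a, dtype=float)
        cb = np.asarray(self.conc_b, dtype=float)
        if resp.shape != (len(ca), len(cb)):
            raise ValueError("response shape must match concentration vectors")
        if not np.all(np.isfinite(resp)):
            raise ValueError("response grid must be finite")
        if abs(resp[0, 0]) > 1e-6:
            raise ValueError("vehicle cell response[0][0] must be ~0")
        for v, name in ((ca, "conc_a"), (cb, "conc_b")):
            if v[0] != 0 or np.any(np.diff(v[1:]) <= 0):
                raise ValueError(f"{name} must start at 0 and increase strictly after it")
        object.__setattr__(self, "conc_a", ca)
        object.__setattr__(self, "conc_b", cb)
        object.__setattr__(self, "response", resp)


@dataclass(frozen=True)
class SynergySurface:
    """Reference expectation, observed-minus-expected excess, and its summary."""

    expected: np.ndarray
    excess: np.ndarray
    summary: float
    model: str


def excess_surface(
    matrix: DoseResponseMatrix,
    model: str = "bliss",
    single_agent_responses: tuple | None = None,
) -> SynergySurface:
    """Observed minus reference-model expectation over the matrix.

    The expected grid is composed cell-wise from the single-agent margins
    (taken from the matrix's zero-dose row/column unless supplied).  The
    summary is the mean excess over the 81 cells where both doses are
    nonzero; positive excess means more inhibition than the non-interaction
    reference, i.e. synergy.
    """
    if model not in _REFERENCE_MODELS:
        raise ValueError(f"unknown reference model {model!r}; choose from {sorted(_REFERENCE_MODELS)}")
    if single_agent_responses is None:
        resp_a = matrix.response[:, 0]
        resp_b = matrix.response[0, :]
    else:
        resp_a, resp_b = (np.asarray(v, dtype=float) for v in single_agent_responses)
        if len(resp_a) != matrix.response.shape[0] or len(resp_b) != matrix.response.shape[1]:
            raise ValueError("single-agent vectors must align with the matrix grids")
    fn = _REFERENCE_MODELS[model]
    expected = fn(resp_a[:, None], resp_b[None, :])
    excess = matrix.response - expected
    summary = float(np.mean(excess[1:, 1:]))
    return SynergySurface(expected=expected, excess=excess, summary=summary, model=model)


def simulate_matrix(
    compound_a: Compound,
    compound_b: Compound,
    gamma: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate: int = 1,
    kappa: float = DEFAULT_KAPPA,
    slope: float = 1.0,
    e_max: float = 0.7,
) -> DoseResponseMatrix:
    """Synthetic combination block consistent with a target gamma.

    Margins follow each compound's Hill curve on its own IC50-centred grid;
    interior cells are the Bliss composition of the margins plus an excess
    inhibition ``kappa * (1 - gamma)`` and optional Gaussian noise, clipped
    to [0, 1].  gamma = 1 reproduces an exactly-Bliss (additive) surface.
    """
    if not 0 <= gamma <= 2:
        raise ValueError("gamma must lie in [0, 2]")
    key = make_key(compound_a.id, compound_b.id)
    conc_a = concentration_grid(compound_a.log_ic50)
    conc_b = concentration_grid(compound_b.log_ic50)
    resp_a = hill_response(conc_a, 10.0 ** compound_a.log_ic50, slope, e_max)
    resp_b = hill_response(conc_b, 10.0 ** compound_b.log_ic50, slope, e_max)
    grid = bliss_expected(resp_a[:, None], resp_b[None, :])
    interior = np.zeros_like(grid)
    interior[1:, 1:] = kappa * (1.0 - gamma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=grid.shape)
        noise[0, 0] = 0.0
        interior = interior + noise
    response = np.clip(grid + interior, 0.0, 1.0)
    response[0, 0] = 0.0
    return DoseResponseMatrix(key=key, conc_a=conc_a, conc_b=conc_b, response=response, replicate=replicate)
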