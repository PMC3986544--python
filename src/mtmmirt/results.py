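"""Shared fit-result container used by all estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .model import ModelParameters

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Point estimates plus bookkeeping from one estimator run.

    ``diagnostics`` holds named scalars (gradient norms, acceptance
    rates, chain spread, ...).  Estimators that produce draws attach
    them via ``chain`` (parameter draws, one row per kept iteration) and
    ``chain_se`` (Monte Carlo standard error per parameter).
    """

    estimates: ModelParameters
    log_likelihood: float
    converged: bool
    n_iterations: int
    estimator_tag: str
    diagnostics: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None
    chain: Optional[Any] = None  # pandas.DataFrame of draws when applicable
    chain_se: Optional[np.ndarray] = None
    aux: dict = field(default_factory=dict)  # estimator-specific arrays

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.log_likelihood):
            raise ValueError("a converged fit must report a finite log-likelihood")
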