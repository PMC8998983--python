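"""Evaluation metrics and the compound-screening ranking.

RMSE is the root of the mean squared difference between predicted and
observed affinities.  R-squared is reported in its residual form
1 - SS_res / SS_tot, which can be negative for predictors worse than the
mean; the regression form SS_reg / SS_tot is also computed (the two
coincide only for unbiased least-squares fits) and exposed as ``r2_alt``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class EvalResult:
    rmse: float
    r2: float
    r2_alt: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("empty input")
    if obs.size != pred.size:
        raise ValueError(f"length mismatch: {obs.size} observed vs {pred.size} predicted")
    return obs, pred


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    obs, pred = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """1 - SS_residual / SS_totality; may be negative; needs non-constant obs."""
    obs, pred = _check_pair(observed, predicted)
    if obs.size < 2:
        raise ValueError("r_squared needs at least 2 samples")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("zero total variance in observed values")
    ss_res = float(((obs - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot

def r_squared_regression(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """SS_regression / SS_totality variant (differs for biased predictors)."""
    obs, pred = _check_pair(observed, predicted)
    if obs.size < 2:
        raise ValueError("r_squared needs at least 2 samples")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("zero total variance in observed values")
    ss_reg = float(((pred - obs.mean()) ** 2).sum())
    return ss_reg / ss_tot


def evaluate(observed: Sequence[float], predicted: Sequence[float]) -> EvalResult:
    obs, pred = _check_pair(observed, predicted)
    return EvalResult(rmse=rmse(obs, pred), r2=r_squared(obs, pred),
                      r2_alt=r_squared_regression(obs, pred), n=int(obs.size))


@dataclass(frozen=True)
class ScreenEntry:
    rank: int            # 1 = predicted strongest binder; failures ranked last
    compound_id: str
    smiles: str
    score: float         # predicted affinity (log10 IC50); lower = stronger
    status: str          # "ok" | "failed: <reason>"


def screen_compounds(predict: Callable[[str], float], compounds: Sequence[str],
                     ids: Sequence[str] | None = None) -> list[ScreenEntry]:
    """Rank candidate compounds against one protein, strongest first.

    ``predict`` maps a SMILES string to a predicted affinity on the log-IC50
    scale, so *lower* scores rank first.  Unscorable compounds are kept in
    the output with a failure status and sorted after all scored ones; ties
    and failures preserve input order.  The result is always a permutation
    of the input.
    """
    if len(compounds) == 0:
        raise ValueError("no compounds to screen")
    if ids is None:
        ids = [f"cmpd{i}" for i in range(len(compounds))]
    scored: list[tuple[float, int, str, str, str]] = []
    for i, smi in enumerate(compounds):
        try:
            score = float(predict(smi))
            scored.append((score, i, ids[i], smi, "ok"))
        except Exception as exc:  # noqa: BLE001 - failure is part of the contract
            scored.append((np.inf, i, ids[i], smi, f"failed: {exc}"))
    scored.sort(key=lambda item: (item[0], item[1]))
    return [
        ScreenEntry(rank=rank + 1, compound_id=cid, smiles=smi,
                    score=score, status=status)
        for rank, (score, _, cid, smi, status) in enumerate(scored)
    ]
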