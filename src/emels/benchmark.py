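"""One-step-ahead predictive benchmark over the three forecasting tasks.

Given fitted models and a (train, task-1 holdout, new-persons) split, this
module produces the accuracy/precision grid used to compare models: for
every model and task the mean squared forecast error (with its standard
error) and, where a forecast-error variance exists (non-tree models), the
mean forecast-error standard deviation sigma_F.

Task 1 forecasts the held-out occasion of each training person; Task 2
forecasts the last occasion of each new person from fixed effects alone;
Task 3 first estimates each new person's random effects from their earlier
occasions, then forecasts their last occasion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, PersonSeries
from .model import LocationScaleResults
from .prediction import evaluate_forecasts, forecast
from .tree import EMELSTreeResults

__all__ = ["one_step_table", "task_forecasts"]


def _subset_row(fit, x_row, full_names):
    if isinstance(fit, EMELSTreeResults):
        return x_row
    idx = [full_names.index(n) for n in fit.beta_names]
    return x_row[idx]


def _subset_series(fit, series, full_names):
    if isinstance(fit, EMELSTreeResults):
        return series
    idx = [full_names.index(n) for n in fit.beta_names]
    return PersonSeries(series.person_id, series.times, series.y,
                        series.X[:, idx], series.Z)


def _one_forecast(fit, x_row, H, task, series, with_variance):
    if isinstance(fit, EMELSTreeResults):
        return fit.forecast(x_row, H=H, task=task, series=series)
    return forecast(fit, x_row, H=H, task=task, series=series,
                    with_variance=with_variance)


def task_forecasts(fit, task: int, train: LongitudinalDataset,
                   holdout: LongitudinalDataset,
                   newpersons: LongitudinalDataset, full_names=None,
                   with_variance: bool = True):
    """(observed, forecasts) pairs for one model and one task."""
    full_names = full_names or list(train.predictor_names)
    obs, fcs = [], []
    if task == 1:
        by_id = {s.person_id: s for s in train.series}
        for h in holdout.series:
            s = by_id.get(h.person_id)
            if s is None:
                continue
            H = int(h.times[0] - s.times[-1])
            obs.append(h.y[0])
            fcs.append(_one_forecast(
                fit, _subset_row(fit, h.X[0], full_names), H, 1,
                _subset_series(fit, s, full_names), with_variance))
        return np.array(obs), fcs
    for s in newpersons.series:
        if task == 2:
            obs.append(s.y[-1])
            fcs.append(_one_forecast(
                fit, _subset_row(fit, s.X[-1], full_names), 1, 2, None,
                with_variance))
        else:
            if s.n_obs < 2:
                continue
            past = PersonSeries(s.person_id, s.times[:-1], s.y[:-1],
                                s.X[:-1], s.Z[:-1])
            obs.append(s.y[-1])
            fcs.append(_one_forecast(
                fit, _subset_row(fit, s.X[-1], full_names), 1, 3,
                _subset_series(fit, past, full_names), with_variance))
    return np.array(obs), fcs


def one_step_table(fits: dict, train: LongitudinalDataset,
                   holdout: LongitudinalDataset,
                   newpersons: LongitudinalDataset,
                   tasks=(1, 2, 3)) -> pd.DataFrame:
    """MSE (with SE) and mean sigma_F per model x task.

    ``fits`` maps model labels to fitted results (mixed-model or tree).
    sigma_F is reported only for models with an available forecast-error
    variance.
    """
    rows = []
    full_names = list(train.predictor_names)
    for label, fit in fits.items():
        with_var = (not isinstance(fit, EMELSTreeResults)
                    and fit.se_available)
        for task in tasks:
            obs, fcs = task_forecasts(fit, task, train, holdout, newpersons,
                                      full_names, with_variance=with_var)
            if len(fcs) == 0:
                continue
            mse, mse_se, msf = evaluate_forecasts(obs, fcs)
            rows.append({"model": label, "task": task, "n_forecasts":
                         len(fcs), "mse": mse, "mse_se": mse_se,
                         "mean_sigma_F": msf})
    return pd.DataFrame(rows)
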