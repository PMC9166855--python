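"""Long-format longitudinal data containers and preprocessing.

The package works on data in "long" format: one row per person-occasion with
a person identifier, an integer occasion index, a numeric outcome, and any
number of numeric predictor columns.  Occasions within a person must be
consecutive integers -- the AR(1) residual process assumes equally spaced
measurements, and a silent gap would silently corrupt the rho^|lag|
covariance semantics, so gaps are a hard error rather than a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PersonSeries",
    "LongitudinalDataset",
    "read_long_csv",
    "write_long_csv",
    "preprocess_predictors",
    "split_train_test",
]

INTERCEPT_NAME = "const"


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Data violate a structural invariant (duplicates, gaps, NaNs...)."""


@dataclass
class PersonSeries:
    """One person's outcome series with fixed- and random-effect designs.

    Attributes
    ----------
    person_id : hashable
        Opaque identifier.
    times : ndarray of int, shape (T,)
        Occasion indices; strictly increasing consecutive integers.
    y : ndarray, shape (T,)
        Outcome vector.
    X : ndarray, shape (T, p+1)
        Fixed-effect design (leading intercept column when built by
        :func:`read_long_csv`).
    Z : ndarray, shape (T, k)
        Random-effect design for the mean structure (a column of ones for
        the random-intercept model).
    """

    person_id: object
    times: np.ndarray
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.validate()

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    def validate(self) -> None:
        T = self.y.shape[0]
        if T < 1:
            raise ValidationError(f"person {self.person_id!r}: empty series")
        if self.times.shape[0] != T or self.X.shape[0] != T or self.Z.shape[0] != T:
            raise ValidationError(
                f"person {self.person_id!r}: row counts of times/y/X/Z differ"
            )
        d = np.diff(self.times)
        if np.any(d != 1):
            gap = int(np.flatnonzero(d != 1)[0])
            raise ValidationError(
                f"person {self.person_id!r}: occasion indices must be consecutive "
                f"integers; gap after time {self.times[gap]}"
            )
        for name, arr in (("y", self.y), ("X", self.X), ("Z", self.Z)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"person {self.person_id!r}: non-finite values in {name}"
                )


@dataclass
class LongitudinalDataset:
    """A collection of :class:`PersonSeries` sharing one design layout."""

    series: list
    predictor_names: list
    preprocessing_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.person_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValidationError("person_ids are not unique")
        for s in self.series:
            if s.X.shape[1] != len(self.predictor_names):
                raise ValidationError(
                    f"person {s.person_id!r}: X has {s.X.shape[1]} columns, "
                    f"expected {len(self.predictor_names)}"
                )

    @property
    def n_persons(self) -> int:
        return len(self.series)

    @property
    def n_total(self) -> int:
        return sum(s.n_obs for s in self.series)

    def person(self, person_id) -> PersonSeries:
        for s in self.series:
            if s.person_id == person_id:
                return s
        raise KeyError(person_id)

    def column(self, name: str) -> np.ndarray:
        """Stacked values of one predictor column across all rows."""
        j = self.predictor_names.index(name)
        return np.concatenate([s.X[:, j] for s in self.series])

    def to_frame(self, outcome_col="y", id_col="id", time_col="time") -> pd.DataFrame:
        frames = []
        for s in self.series:
            d = {id_col: s.person_id, time_col: s.times, outcome_col: s.y}
            for j, name in enumerate(self.predictor_names):
                if name == INTERCEPT_NAME:
                    continue
                d[name] = s.X[:, j]
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)

    def select_predictors(self, names) -> "LongitudinalDataset":
        """Restrict X to the given columns (used for Lasso refits)."""
        idx = [self.predictor_names.index(n) for n in names]
        new = [
            PersonSeries(s.person_id, s.times, s.y, s.X[:, idx], s.Z)
            for s in self.series
        ]
        return LongitudinalDataset(new, list(names), dict(self.preprocessing_record))

    def with_design(self, X_blocks, names) -> "LongitudinalDataset":
        """Replace X by externally built blocks (used for tree dummies)."""
        if len(X_blocks) != len(self.series):
            raise ValidationError("one X block per person required")
        new = [
            PersonSeries(s.person_id, s.times, s.y, Xb, s.Z)
            for s, Xb in zip(self.series, X_blocks)
        ]
        return LongitudinalDataset(new, list(names), dict(self.preprocessing_record))


def dataset_from_frame(
    df: pd.DataFrame,
    outcome_col: str,
    id_col: str,
    time_col: str,
    predictor_cols,
    add_intercept: bool = True,
) -> LongitudinalDataset:
    """Build a dataset from a long-format DataFrame (see :func:`read_long_csv`)."""
    needed = [outcome_col, id_col, time_col, *predictor_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    for c in [outcome_col, *predictor_cols]:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric value in column {c!r} at row {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(f"missing value in column {c!r} at row {row}")
        df = df.assign(**{c: vals})
    if df.duplicated([id_col, time_col]).any():
        dup = df[df.duplicated([id_col, time_col])].iloc[0]
        raise ValidationError(
            f"duplicate (id, time) pair: ({dup[id_col]!r}, {dup[time_col]!r})"
        )
    series = []
    for pid, g in df.groupby(id_col, sort=False):
        g = g.sort_values(time_col)
        Xcols = [g[c].to_numpy(float) for c in predictor_cols]
        T = len(g)
        if add_intercept:
            Xcols = [np.ones(T)] + Xcols
        X = np.column_stack(Xcols) if Xcols else np.ones((T, 1))
        series.append(
            PersonSeries(
                person_id=pid,
                times=g[time_col].to_numpy(int),
                y=g[outcome_col].to_numpy(float),
                X=X,
                Z=np.ones((T, 1)),
            )
        )
    names = ([INTERCEPT_NAME] if add_intercept else []) + list(predictor_cols)
    return LongitudinalDataset(series, names)


def read_long_csv(
    path,
    outcome_col: str,
    id_col: str,
    time_col: str,
    predictor_cols,
    add_intercept: bool = True,
) -> LongitudinalDataset:
    """Read long-format CSV into a :class:`LongitudinalDataset`.

    One :class:`PersonSeries` is built per unique id, rows ordered by the
    occasion index; an intercept column is prepended to X and the Z design is
    a column of ones (random intercept).
    """
    df = pd.read_csv(path)
    return dataset_from_frame(
        df, outcome_col, id_col, time_col, predictor_cols, add_intercept
    )


def write_long_csv(ds: LongitudinalDataset, path, outcome_col="y", id_col="id",
                   time_col="time") -> None:
    """Companion writer emitting the same long CSV dialect."""
    ds.to_frame(outcome_col, id_col, time_col).to_csv(path, index=False)


def preprocess_predictors(
    ds: LongitudinalDataset,
    time_varying,
    standardize: bool = False,
) -> LongitudinalDataset:
    """Within-person center time-varying predictors; optionally z-standardize.

    Each named time-varying column is replaced by its person-mean-centered
    version and the person means are appended as new time-constant columns
    (suffix ``_pm``).  With ``standardize=True`` every non-intercept predictor
    is divided by its standard deviation across all rows (population SD,
    computed after centering).  All constants go into
    ``preprocessing_record`` so the transformation is reproducible.
    """
    for c in time_varying:
        if c not in ds.predictor_names:
            raise SchemaError(f"unknown predictor column {c!r}")
    record = {"centered": list(time_varying), "person_means": {}, "sds": {}}
    names = list(ds.predictor_names)
    pm_names = [f"{c}_pm" for c in time_varying]
    new_series = []
    for s in ds.series:
        X = s.X.copy()
        pm_cols = []
        for c in time_varying:
            j = names.index(c)
            m = float(X[:, j].mean())
            record["person_means"].setdefault(c, {})[s.person_id] = m
            X[:, j] = X[:, j] - m
            pm_cols.append(np.full(s.n_obs, m))
        X = np.column_stack([X] + pm_cols) if pm_cols else X
        new_series.append(PersonSeries(s.person_id, s.times, s.y, X, s.Z))
    all_names = names + pm_names
    out = LongitudinalDataset(new_series, all_names, record)
    if standardize:
        stacked = {n: out.column(n) for n in all_names if n != INTERCEPT_NAME}
        scaled_series = []
        sds = {}
        for n, v in stacked.items():
            sd = float(v.std())  # population SD (ddof=0); recorded below
            if sd == 0.0:
                raise ValidationError(
                    f"cannot standardize zero-variance column {n!r}"
                )
            sds[n] = sd
        for s in out.series:
            X = s.X.copy()
            for j, n in enumerate(all_names):
                if n != INTERCEPT_NAME:
                    X[:, j] = X[:, j] / sds[n]
            scaled_series.append(PersonSeries(s.person_id, s.times, s.y, X, s.Z))
        record["sds"] = sds
        record["sd_ddof"] = 0
        out = LongitudinalDataset(scaled_series, all_names, record)
    return out


def split_train_test(ds: LongitudinalDataset, n_train_persons: int,
                     n_train_times: int):
    """Split into (train, task-1 holdout rows, new-person dataset).

    ``train`` holds the first ``n_train_persons`` persons restricted to their
    first ``n_train_times`` occasions; ``test_task1`` their remaining rows;
    ``test_newpersons`` all other persons with their full series.
    """
    if n_train_persons > ds.n_persons:
        raise ValidationError(
            f"n_train_persons={n_train_persons} exceeds I={ds.n_persons}"
        )
    train, holdout, newp = [], [], []
    for i, s in enumerate(ds.series):
        if i < n_train_persons:
            t = min(n_train_times, s.n_obs)
            train.append(
                PersonSeries(s.person_id, s.times[:t], s.y[:t], s.X[:t], s.Z[:t])
            )
            if t < s.n_obs:
                holdout.append(
                    PersonSeries(
                        s.person_id, s.times[t:], s.y[t:], s.X[t:], s.Z[t:]
                    )
                )
        else:
            newp.append(s)
    names = list(ds.predictor_names)
    rec = dict(ds.preprocessing_record)
    train_ds = LongitudinalDataset(train, names, rec)
    holdout_ds = LongitudinalDataset(holdout, names, rec) if holdout else \
        LongitudinalDataset([], names, rec)
    new_ds = LongitudinalDataset(newp, names, rec) if newp else \
        LongitudinalDataset([], names, rec)
    return train_ds, holdout_ds, new_ds
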