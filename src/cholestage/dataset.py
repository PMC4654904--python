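"""Time-course data model, long-format I/O, ddCt preprocessing and factor normalization.

The central container is :class:`TimeCourseDataset`: a factor x time x replicate
value tensor with per-factor metadata.  Factors are any measured parameter of
the study system — biochemical serum markers (modality ``B``), histological
stains (``H``), immunostaining cell counts (``A``) or qPCR transcripts
(``transcript``).  Transcripts additionally carry a gene-panel tag (ADME,
fibrosis or inflammation); non-transcript factors carry ``none``.

Missing cells are represented as NaN and all downstream statistics use
pairwise-complete observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODALITIES = ("B", "H", "A", "transcript")
PANELS = ("ADME", "fibrosis", "inflammation", "none")

#: The study design's sampling grid in hours: sham control at 0 h, then
#: 6, 12, 18, 30 h and 2, 5, 14 days post-ligation.
DEFAULT_TIMES_H = (0.0, 6.0, 12.0, 18.0, 30.0, 48.0, 120.0, 336.0)

CSV_COLUMNS = ["factor_id", "modality", "panel", "time_h", "replicate", "value"]


class DatasetError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass(frozen=True)
class FactorMeta:
    """Identity and provenance of a single measured factor."""

    factor_id: str
    modality: str = "transcript"
    panel: str = "inflammation"

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise DatasetError(
                f"factor {self.factor_id!r}: unknown modality {self.modality!r}"
            )
        if self.panel not in PANELS:
            raise DatasetError(
                f"factor {self.factor_id!r}: unknown panel {self.panel!r}"
            )
        if self.modality == "transcript" and self.panel == "none":
            raise DatasetError(
                f"transcript factor {self.factor_id!r} must carry a gene panel"
            )
        if self.modality != "transcript" and self.panel != "none":
            raise DatasetError(
                f"non-transcript factor {self.factor_id!r} must carry panel 'none'"
            )


@dataclass
class TimeCourseDataset:
    """Factor x time x replicate tensor of measurements.

    Parameters
    ----------
    factors:
        Per-factor metadata; ``factor_id`` must be unique.
    times:
        Strictly increasing time points in hours; the first must be 0
        (sham/control).
    values:
        Array of shape ``(n_factors, n_times, n_replicates)``; NaN marks a
        missing cell.
    """

    factors: list[FactorMeta]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate factor ids: {dupes}")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise DatasetError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise DatasetError("time points must be strictly increasing")
        if self.times[0] != 0:
            raise DatasetError("first time point must be 0 h (control)")
        if self.values.shape[:2] != (len(self.factors), len(self.times)):
            raise DatasetError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.factors)} factors x {len(self.times)} times"
            )
        if self.values.shape[2] < 2:
            raise DatasetError("need at least 2 replicates per time point")
        self._index = {f.factor_id: k for k, f in enumerate(self.factors)}

    # -- basic accessors ---------------------------------------------------
    @property
    def factor_ids(self) -> list[str]:
        return [f.factor_id for f in self.factors]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean tensor flagging missing (NaN) cells."""
        return np.isnan(self.values)

    def factor_values(self, factor_id: str) -> np.ndarray:
        """The ``(n_times, n_replicates)`` value block of one factor."""
        try:
            k = self._index[factor_id]
        except KeyError:
            raise KeyError(f"unknown factor {factor_id!r}") from None
        return self.values[k]

    def subset(self, factor_ids) -> "TimeCourseDataset":
        """Dataset restricted to ``factor_ids`` (in the given order)."""
        idx = [self._index[f] for f in factor_ids]
        return replace(
            self,
            factors=[self.factors[i] for i in idx],
            values=self.values[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with one row per (factor, time, replicate) cell."""
        k, i, r = np.meshgrid(
            np.arange(self.n_factors),
            np.arange(self.n_times),
            np.arange(self.n_replicates),
            indexing="ij",
        )
        ids = np.array(self.factor_ids)
        modality = np.array([f.modality for f in self.factors])
        panel = np.array([f.panel for f in self.factors])
        df = pd.DataFrame(
            {
                "factor_id": ids[k.ravel()],
                "modality": modality[k.ravel()],
                "panel": panel[k.ravel()],
                "time_h": self.times[i.ravel()],
                "replicate": r.ravel() + 1,
                "value": self.values.ravel(),
            }
        )
        return df


@dataclass
class NormalizedDataset(TimeCourseDataset):
    """A :class:`TimeCourseDataset` whose factors are mean-centred and
    range-scaled: each non-degenerate factor has grand mean 0 and
    ``max - min = 1`` over all observed cells."""


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def read_dataset(path, sep: str = ",") -> TimeCourseDataset:
    """Read a long-format CSV/TSV into a validated :class:`TimeCourseDataset`.

    Expected header: ``factor_id, modality, panel, time_h, replicate, value``.
    Duplicate (factor, time, replicate) triples are rejected; absent cells are
    flagged missing (NaN).  Malformed numeric fields raise a parse error
    naming the offending line.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"{path}: missing columns {missing_cols}")

    def _numeric(col):
        # python float() parsing round-trips %.17g output exactly (the
        # pandas fast parser can be off by one ulp)
        out = np.empty(len(df))
        for pos, (idx, raw) in enumerate(df[col].items()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                out[pos] = np.nan
                continue
            try:
                out[pos] = float(raw)
            except (TypeError, ValueError):
                # +2: header line plus 1-based numbering
                raise DatasetError(
                    f"{path}: malformed {col!r} value {raw!r} "
                    f"on line {int(idx) + 2}"
                ) from None
        return pd.Series(out, index=df.index)

    df = df.assign(
        time_h=_numeric("time_h"),
        replicate=_numeric("replicate"),
        value=_numeric("value"),
    )
    dup = df.duplicated(subset=["factor_id", "time_h", "replicate"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise DatasetError(
            f"duplicate measurement for (factor {row.factor_id!r}, "
            f"time {row.time_h} h, replicate {int(row.replicate)})"
        )

    factor_ids = list(dict.fromkeys(df["factor_id"]))
    times = np.array(sorted(df["time_h"].unique()))
    reps = np.array(sorted(df["replicate"].unique().astype(int)))
    n_r = len(reps)
    rep_pos = {r: j for j, r in enumerate(reps)}
    time_pos = {t: i for i, t in enumerate(times)}

    meta = {}
    for fid, sub in df.groupby("factor_id", sort=False):
        mods = sub["modality"].unique()
        pans = sub["panel"].unique()
        if len(mods) > 1 or len(pans) > 1:
            raise DatasetError(f"factor {fid!r} has inconsistent metadata")
        meta[fid] = FactorMeta(fid, mods[0], pans[0])

    values = np.full((len(factor_ids), len(times), n_r), np.nan)
    fpos = {f: k for k, f in enumerate(factor_ids)}
    values[
        df["factor_id"].map(fpos).to_numpy(),
        df["time_h"].map(time_pos).to_numpy(),
        df["replicate"].astype(int).map(rep_pos).to_numpy(),
    ] = df["value"].to_numpy()

    n_cells = values.size
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing}/{n_cells} cells missing after reading {path}",
            stacklevel=2,
        )
    return TimeCourseDataset([meta[f] for f in factor_ids], times, values)


def write_dataset(data: TimeCourseDataset, path, sep: str = ",") -> None:
    """Write ``data`` as long-format CSV (missing cells omitted)."""
    df = data.to_frame()
    df = df[~df["value"].isna()]
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ddCt relative quantification
# ---------------------------------------------------------------------------

def ddct_normalize(
    ct: pd.DataFrame,
    reference_gene: str,
    control_samples,
) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) from raw qPCR cycle-threshold values.

    Per sample, dCt = Ct(gene) - Ct(reference); ddCt subtracts the mean dCt
    over the control samples, so the control group's geometric-mean relative
    expression is exactly 1.  Expression is normalized to a housekeeping
    reference gene (Gapdh in the study design).

    Parameters
    ----------
    ct:
        Long table with columns ``gene``, ``sample``, ``ct``.
    reference_gene:
        Housekeeping gene id; must be measured in every sample.
    control_samples:
        Sample ids forming the control (e.g. sham/0 h) group.

    Returns
    -------
    DataFrame with columns ``gene``, ``sample``, ``rel_expr``; non-finite Ct
    cells propagate as NaN (flagged missing).
    """
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct.columns):
        raise DatasetError(f"ct table needs columns {sorted(required)}")
    control_samples = list(control_samples)
    if not control_samples:
        raise DatasetError("need at least one control sample")

    ct = ct.copy()
    ct["ct"] = pd.to_numeric(ct["ct"], errors="coerce")
    ct.loc[~np.isfinite(ct["ct"]), "ct"] = np.nan

    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    samples = ct["sample"].unique()
    absent = [s for s in samples if s not in ref.index or np.isnan(ref.get(s, np.nan))]
    if absent:
        raise DatasetError(
            f"reference gene {reference_gene!r} missing in samples {absent}"
        )

    out = ct[ct["gene"] != reference_gene].copy()
    out["dct"] = out["ct"].to_numpy() - ref.loc[out["sample"]].to_numpy()
    ctrl_mean = (
        out[out["sample"].isin(control_samples)]
        .groupby("gene")["dct"]
        .mean()
    )
    out["ddct"] = out["dct"] - out["gene"].map(ctrl_mean).to_numpy()
    out["rel_expr"] = 2.0 ** (-out["ddct"])
    return out[["gene", "sample", "rel_expr"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# factor normalization
# ---------------------------------------------------------------------------

def normalize_factors(data: TimeCourseDataset) -> NormalizedDataset:
    """Per-factor affine normalization to grand mean 0 and range 1.

    For factor k with observations f_k(t_i, r):

        fbar_k(t_i, r) = (f_k(t_i, r) - <f_k>) / (max f_k - min f_k)

    where <f_k> is the mean over all N_t * N_r observed cells.  The transform
    is invariant under positive affine rescaling of the raw factor and
    idempotent.  Missing cells stay missing.

    Raises
    ------
    DatasetError
        If a factor is constant (max = min: division by zero) or has fewer
        than 2 finite values.
    """
    values = data.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        grand = np.nanmean(values, axis=(1, 2))
        vmax = np.nanmax(values, axis=(1, 2))
        vmin = np.nanmin(values, axis=(1, 2))
    n_finite = np.isfinite(values).sum(axis=(1, 2))
    bad = [
        f.factor_id
        for f, n, hi, lo in zip(data.factors, n_finite, vmax, vmin)
        if n < 2 or hi == lo
    ]
    if bad:
        raise DatasetError(
            f"cannot normalize constant/degenerate factors: {bad}"
        )
    rng = (vmax - vmin)[:, None, None]
    normed = (values - grand[:, None, None]) / rng
    return NormalizedDataset(list(data.factors), data.times.copy(), normed)
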