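"""Monte-Carlo merging and the serial-crystallography quality metric set.

Observations from many stills are averaged per unique reflection (unweighted
Monte-Carlo mean) after a per-pattern linear scaling; precision and signal
metrics (R_split, CC_1/2, CC*, CC_ano, CC_anoref, SNR, completeness,
redundancy) are computed overall and in equal-volume resolution shells from
half-dataset splits by pattern parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .errors import InvalidInputError, UndefinedMetricError
from .truth import StructureFactorSet

log = logging.getLogger(__name__)

KEYS = ["ah", "ak", "al"]


@dataclass
class MergedDataset:
    """Merged unique intensities with half-dataset splits.

    ``frame`` has one row per unique (ASU triple, Friedel branch) with
    columns I, sigma, nobs, I_even, n_even, I_odd, n_odd, d, centric.
    """

    frame: pd.DataFrame
    cell: geometry.UnitCell
    symmetry: str
    friedel_separate: bool
    n_patterns: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def common_halves(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["n_even"] > 0) & (f["n_odd"] > 0)]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# h k l friedel I sigma nobs\n")
            for row in self.frame.itertuples():
                fh.write(
                    f"{row.ah} {row.ak} {row.al} {'-' if row.minus else '+'} "
                    f"{row.I:.17g} {row.sigma:.17g} {row.nobs}\n"
                )


def scale_patterns(obs: pd.DataFrame, min_ref_obs: int = 2) -> pd.DataFrame:
    """Two-pass per-pattern linear scaling against the unscaled merge.

    Pass 1 merges everything into a reference; pass 2 fits one least-squares
    scale k_p = sum(I_p I_ref) / sum(I_ref^2) per pattern over reflections
    whose reference has at least ``min_ref_obs`` observations, then divides.
    The median scale is normalised to 1. Patterns sharing no usable reference
    reflection keep scale 1 (logged).
    """
    if obs["pattern"].nunique() < 2:
        raise InvalidInputError("per-pattern scaling needs at least two patterns")
    ref = obs.groupby(KEYS + ["minus"], sort=False)["intensity"].agg(["mean", "size"])
    joined = obs.join(ref, on=KEYS + ["minus"])
    usable = joined["size"] >= min_ref_obs
    sub = joined[usable]
    num = (sub["intensity"] * sub["mean"]).groupby(sub["pattern"]).sum()
    den = (sub["mean"] ** 2).groupby(sub["pattern"]).sum()
    k = (num / den).replace([np.inf, -np.inf], np.nan)
    all_patterns = pd.Index(obs["pattern"].unique(), name="pattern")
    k = k.reindex(all_patterns)
    bad = k.isna() | (k <= 0)
    if bad.any():
        log.warning("%d pattern(s) had no usable reference reflections; scale 1", bad.sum())
        k[bad] = np.nan
    k = k / np.nanmedian(k)
    k = k.fillna(1.0)
    out = obs.copy()
    factors = k.reindex(out["pattern"]).to_numpy()
    out["intensity"] = out["intensity"] / factors
    out["sigma"] = out["sigma"] / factors
    return out


def merge(
    obs: pd.DataFrame,
    cell: geometry.UnitCell,
    symmetry: str = "",
    friedel_separate: bool = True,
    outlier_sd: float = 4.0,
) -> MergedDataset:
    """Unweighted Monte-Carlo merge with a single-pass outlier clip.

    Observations beyond ``outlier_sd`` sample standard deviations from their
    group mean are rejected once (groups of >= 4 only). Even/odd half merges
    split patterns by index parity. Merged sigma is the standard error
    sd/sqrt(n) for n >= 2, else the observation's own sigma.
    """
    if len(obs) == 0:
        raise InvalidInputError("no observations to merge")
    keys = KEYS + ["minus"] if friedel_separate else KEYS
    work = obs[keys + ["pattern", "intensity", "sigma"]].copy()
    if not friedel_separate:
        work["minus"] = False
    grp = work.groupby(keys, sort=False)["intensity"]
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    n = grp.transform("size")
    keep = (n < 4) | (sd == 0) | ((work["intensity"] - mean).abs() <= outlier_sd * sd)
    work = work[keep]

    even = work["pattern"] % 2 == 0
    gb = work.groupby(KEYS + ["minus"], sort=False)
    agg = gb.agg(
        I=("intensity", "mean"),
        sd=("intensity", "std"),
        nobs=("intensity", "size"),
        sigma_own=("sigma", "first"),
    )
    half = (
        work.assign(even=even)
        .groupby(KEYS + ["minus", "even"], sort=False)["intensity"]
        .agg(["mean", "size"])
        .unstack("even")
    )
    for parity, name in ((True, "even"), (False, "odd")):
        if ("mean", parity) in half.columns:
            agg[f"I_{name}"] = half[("mean", parity)]
            agg[f"n_{name}"] = half[("size", parity)].fillna(0).astype(int)
        else:
            agg[f"I_{name}"] = np.nan
            agg[f"n_{name}"] = 0
    agg["sigma"] = np.where(
        agg["nobs"] >= 2, agg["sd"] / np.sqrt(agg["nobs"]), agg["sigma_own"]
    )
    agg = agg.drop(columns=["sd", "sigma_own"]).reset_index()
    B = geometry.reciprocal_basis(cell)
    mil = agg[KEYS].to_numpy()
    agg["d"] = 1.0 / np.linalg.norm(mil @ B.T, axis=1)
    if symmetry:
        sym = geometry.SymmetrySpec.from_symbol(symmetry)
        agg["centric"] = geometry.is_centric(mil, sym)
    else:
        agg["centric"] = False
    return MergedDataset(
        frame=agg,
        cell=cell,
        symmetry=symmetry,
        friedel_separate=friedel_separate,
        n_patterns=int(obs["pattern"].nunique()),
    )


# --------------------------------------------------------------------------
# metrics


def _require_common(frame: pd.DataFrame, n: int = 1) -> pd.DataFrame:
    common = frame[(frame["n_even"] > 0) & (frame["n_odd"] > 0)]
    if len(common) < n:
        raise UndefinedMetricError(
            f"need >= {n} reflections present in both half datasets, have {len(common)}"
        )
    return common


def r_split(merged: MergedDataset | pd.DataFrame) -> float:
    """Half-dataset precision in percent:
    2^(-1/2) sum|I_even - I_odd| / [(1/2) sum(I_even + I_odd)] * 100."""
    frame = merged.frame if isinstance(merged, MergedDataset) else merged
    common = _require_common(frame)
    num = np.abs(common["I_even"] - common["I_odd"]).sum()
    den = 0.5 * (common["I_even"] + common["I_odd"]).sum()
    if den == 0:
        raise UndefinedMetricError("zero summed intensity in half datasets")
    return float(100.0 * num / (np.sqrt(2.0) * den))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise UndefinedMetricError("need >= 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("constant input; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def cc_half(merged: MergedDataset | pd.DataFrame) -> float:
    """Pearson correlation of even- vs odd-half merged intensities."""
    frame = merged.frame if isinstance(merged, MergedDataset) else merged
    common = _require_common(frame, 3)
    return _pearson(common["I_even"].to_numpy(), common["I_odd"].to_numpy())

def cc_star(cc_half_value: float) -> float:
    """Extrapolated full-dataset correlation sqrt(2 c / (1 + c))."""
    if cc_half_value <= -1.0:
        raise InvalidInputError("CC_1/2 must be > -1")
    return float(np.sqrt(2.0 * cc_half_value / (1.0 + cc_half_value)))


def _anomalous_differences(frame: pd.DataFrame, columns) -> pd.DataFrame:
    """Per acentric ASU triple: requested columns for + and - branches."""
    acent = frame[~frame["centric"]]
    plus = acent[~acent["minus"]].set_index(KEYS)[columns]
    minus = acent[acent["minus"]].set_index(KEYS)[columns]
    return plus.join(minus, lsuffix="_p", rsuffix="_m", how="inner")


def cc_ano(merged: MergedDataset) -> float:
    """Correlation of half-dataset anomalous intensity differences.

    dI = I(+) - I(-) per acentric unique, computed separately in the even and
    odd halves; both mates must be present in both halves.
    """
    if not merged.friedel_separate:
        raise InvalidInputError("CC_ano needs a Friedel-separate merge")
    both = merged.frame[(merged.frame["n_even"] > 0) & (merged.frame["n_odd"] > 0)]
    pairs = _anomalous_differences(both, ["I_even", "I_odd"])
    if len(pairs) < 3:
        raise UndefinedMetricError("too few acentric Bijvoet pairs in both halves")
    d_even = pairs["I_even_p"] - pairs["I_even_m"]
    d_odd = pairs["I_odd_p"] - pairs["I_odd_m"]
    return _pearson(d_even.to_numpy(), d_odd.to_numpy())


def cc_anoref(merged: MergedDataset, sf: StructureFactorSet) -> float:
    """Correlation of observed vs expected anomalous amplitude differences.

    Observed |dF| = |sqrt(I+) - sqrt(I-)| from positive merged intensities;
    expected from the ground-truth amplitudes.
    """
    if not merged.friedel_separate:
        raise InvalidInputError("CC_anoref needs a Friedel-separate merge")
    pairs = _anomalous_differences(merged.frame, ["I"])
    pairs = pairs[(pairs["I_p"] > 0) & (pairs["I_m"] > 0)]
    if len(pairs) == 0:
        raise UndefinedMetricError("no acentric pairs with positive merged intensities")
    obs_df = np.abs(np.sqrt(pairs["I_p"]) - np.sqrt(pairs["I_m"]))
    truth_frame = pd.DataFrame(
        {
            "ah": sf.miller[:, 0],
            "ak": sf.miller[:, 1],
            "al": sf.miller[:, 2],
            "dF": np.abs(sf.f_plus - sf.f_minus),
        }
    ).set_index(KEYS)
    joined = obs_df.to_frame("obs").join(truth_frame, how="inner")
    if len(joined) < 3:
        raise UndefinedMetricError("no overlap with the ground-truth set")
    return _pearson(joined["obs"].to_numpy(), joined["dF"].to_numpy())


def snr(merged: MergedDataset | pd.DataFrame) -> float:
    """Mean I/sigma over merged unique reflections."""
    frame = merged.frame if isinstance(merged, MergedDataset) else merged
    ok = frame["sigma"] > 0
    if not ok.any():
        raise UndefinedMetricError("no reflections with positive sigma")
    return float((frame.loc[ok, "I"] / frame.loc[ok, "sigma"]).mean())


def redundancy(merged: MergedDataset | pd.DataFrame) -> float:
    frame = merged.frame if isinstance(merged, MergedDataset) else merged
    return float(frame["nobs"].mean())


def completeness(
    merged: MergedDataset,
    d_max: float,
    d_min: float,
) -> float:
    """Measured fraction (%) of the enumerable unique reflections in a range."""
    sym = geometry.SymmetrySpec.from_symbol(merged.symmetry)
    expected = geometry.enumerate_unique(
        merged.cell, sym, d_max, d_min, friedel_separate=merged.friedel_separate
    )["count"]
    if expected == 0:
        raise UndefinedMetricError("no enumerable reflections in range")
    f = merged.frame
    got = f[(f["d"] >= d_min * (1 - 1e-9)) & (f["d"] <= d_max * (1 + 1e-9))]
    return float(100.0 * len(got) / expected)


def recovery_correlation(
    merged: MergedDataset, sf: StructureFactorSet, n_shells: int = 15
) -> float:
    """Pearson correlation between merged and true intensities.

    A still-merged intensity estimates |F|^2 times the mean Ewald-sweep
    weight of its reflection, a smooth function of resolution; that factor
    is removed by per-shell median scaling (relative shell scaling, as
    half-set comparison tools do) before correlating against |F+-|^2.
    """
    tf = pd.DataFrame(
        {
            "ah": sf.miller[:, 0],
            "ak": sf.miller[:, 1],
            "al": sf.miller[:, 2],
            "Ip": sf.f_plus**2,
            "Im": sf.f_minus**2,
        }
    )
    f = merged.frame.merge(tf, on=KEYS)
    f["itrue"] = np.where(f["minus"], f["Im"], f["Ip"])
    f = f[f["itrue"] > 0]
    if len(f) < 3:
        raise UndefinedMetricError("no overlap with the ground-truth set")
    bounds = shell_boundaries(f["d"].max(), f["d"].min(), n_shells)
    shell = np.digitize(-f["d"].to_numpy(), -bounds[1:-1])
    ratio = pd.Series((f["I"] / f["itrue"]).to_numpy())
    scale = ratio.groupby(shell).transform("median").to_numpy()
    return _pearson((f["I"] / scale).to_numpy(), f["itrue"].to_numpy())


def shell_boundaries(d_max: float, d_min: float, n_shells: int) -> np.ndarray:
    """Equal-volume shells in 1/d^3: boundaries from d_max down to d_min."""
    s = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    return s ** (-1.0 / 3.0)


def shell_table(
    merged: MergedDataset,
    n_shells: int = 10,
    d_max: float | None = None,
    d_min: float | None = None,
    sf: StructureFactorSet | None = None,
) -> pd.DataFrame:
    """Per-resolution-shell quality statistics.

    Metrics that are undefined in a shell (too few reflections) are NaN.
    Completeness uses the absence-free unique enumeration; CC_anoref is
    included when a ground-truth set is supplied.
    """
    f = merged.frame
    d_max = float(d_max if d_max is not None else f["d"].max())
    d_min = float(d_min if d_min is not None else f["d"].min())
    bounds = shell_boundaries(d_max, d_min, n_shells)
    sym = geometry.SymmetrySpec.from_symbol(merged.symmetry) if merged.symmetry else None
    rows = []
    for i in range(n_shells):
        hi_d, lo_d = bounds[i], bounds[i + 1]
        eps = 1e-9
        sel = (f["d"] <= hi_d * (1 + eps)) & (f["d"] > lo_d * (1 + eps))
        if i == n_shells - 1:
            sel = (f["d"] <= hi_d * (1 + eps)) & (f["d"] >= lo_d * (1 - eps))
        sub = MergedDataset(
            frame=f[sel],
            cell=merged.cell,
            symmetry=merged.symmetry,
            friedel_separate=merged.friedel_separate,
            n_patterns=merged.n_patterns,
        )
        row = {"d_max": hi_d, "d_min": lo_d, "n_unique": int(sel.sum())}
        if sym is not None:
            try:
                row["completeness"] = completeness(sub, hi_d, lo_d)
            except UndefinedMetricError:
                row["completeness"] = np.nan
        for name, fn in (
            ("redundancy", redundancy),
            ("snr", snr),
            ("r_split", r_split),
            ("cc_half", cc_half),
            ("cc_ano", cc_ano),
        ):
            try:
                row[name] = fn(sub)
            except (UndefinedMetricError, InvalidInputError):
                row[name] = np.nan
        row["cc_star"] = (
            cc_star(row["cc_half"]) if row.get("cc_half", np.nan) > -1 else np.nan
        )
        if sf is not None:
            try:
                row["cc_anoref"] = cc_anoref(sub, sf)
            except (UndefinedMetricError, InvalidInputError):
                row["cc_anoref"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
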