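"""Dictionary construction, compression, and inner-product matching.

Instead of iteratively fitting each tissue curve, every admissible (AF, MTT)
pair on a discrete grid is pushed through the forward model once (with
DV = 1, since DV only scales the curve), each model curve is divided by its
own L2 norm, and the normalized curves are stored as columns of a t x n
matrix.  A measured curve is estimated by normalizing it and taking the
inner product with every column; the argmax column's (AF, MTT) is the
estimate, and DV is recovered afterwards as the ratio of L2 norms

    DV ~= ||C_L||_2 / ||C_LD||_2

where C_LD is the un-normalized model curve of the best match.  Because
every entry is scored, the search is exhaustive: the reported match is the
global maximum over the grid, with no dependence on an initial guess and no
local-minimum failure mode.

A low-rank compression via randomized SVD is provided for memory-limited
matching: curves and dictionary are projected onto the leading left singular
vectors and inner products are computed in the compressed space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.extmath import randomized_svd

from .model import PerfusionParams, check_times, forward_model
from .inputs import InputFunctions

__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "CompressedDictionary",
    "MatchResult",
    "default_grid",
    "build_dictionary",
    "compress",
    "match",
    "match_arrays",
    "estimate_dv",
    "save_dictionary",
    "load_dictionary",
    "DictionaryMatcher",
]

MTT_EPS = 1e-4  # MTT cannot be 0 (k2 = 1/MTT); degenerate lower grid bound


@dataclass(frozen=True)
class DictionaryGrid:
    """Discrete (AF, MTT) grid over which model curves are generated.

    DV is fixed to 1 during generation — it is a pure scaling property and
    is recovered at match time from the norm ratio.
    """

    af_values: np.ndarray
    mtt_values: np.ndarray
    dv_fixed: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "af_values", np.asarray(self.af_values, dtype=float))
        object.__setattr__(self, "mtt_values", np.asarray(self.mtt_values, dtype=float))
        af, mtt = self.af_values, self.mtt_values
        if af.size == 0 or mtt.size == 0:
            raise ValueError("grid axes must be nonempty")
        if np.any(np.diff(af) <= 0) or np.any(np.diff(mtt) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if af[0] < 0 or af[-1] > 1:
            raise ValueError("AF grid must lie within [0, 1]")
        if mtt[0] <= 0 or mtt[-1] > 100:
            raise ValueError("MTT grid must lie within (0, 100]")
        if self.dv_fixed != 1.0:
            raise ValueError("DV is fixed to 1 in the dictionary")

    @property
    def n_entries(self) -> int:
        return self.af_values.size * self.mtt_values.size

    def param_table(self) -> np.ndarray:
        """(n, 2) array of (AF, MTT) in column order (AF-major, MTT-minor)."""
        af = np.repeat(self.af_values, self.mtt_values.size)
        mtt = np.tile(self.mtt_values, self.af_values.size)
        return np.column_stack([af, mtt])


def default_grid(af_step: float = 0.01, mtt_step: float = 1.0) -> DictionaryGrid:
    """Grid with AF spanning 0–1 and MTT spanning 0.0001–100 s.

    With the default steps (0.01 and 1 s) the AF axis has 101 values and the
    MTT axis has 101 values (the degenerate 0.0001 s entry plus the integers
    1..100), for 10201 entries total.  For other steps the MTT axis is
    {0.0001, step, 2*step, ...} up to 100.
    """
    if af_step <= 0 or mtt_step <= 0:
        raise ValueError("step sizes must be positive")
    n_af = int(round(1.0 / af_step))
    af = np.round(np.arange(n_af + 1) * af_step, 10)
    af = af[af <= 1.0 + 1e-12]
    n_mtt = int(np.floor(100.0 / mtt_step + 1e-9))
    mtt = np.concatenate([[MTT_EPS], np.round(np.arange(1, n_mtt + 1) * mtt_step, 10)])
    return DictionaryGrid(af_values=af, mtt_values=mtt)


@dataclass
class Dictionary:
    """Normalized model-curve dictionary.

    ``entries`` is t x n with unit-L2-norm columns; ``norms`` holds each
    column's pre-normalization L2 norm so that the un-normalized model curve
    (needed for DV recovery) is ``entries[:, j] * norms[j]``.
    """

    grid: DictionaryGrid
    times: np.ndarray
    entries: np.ndarray  # (t, n), unit columns
    norms: np.ndarray  # (n,)
    params: np.ndarray  # (n, 2): AF, MTT per column
    inputs_hash: str = ""

    @property
    def n_entries(self) -> int:
        return self.entries.shape[1]

    def index_frame(self) -> pd.DataFrame:
        """Column index as a DataFrame (column, AF, MTT, norm)."""
        return pd.DataFrame(
            {
                "column": np.arange(self.n_entries),
                "af": self.params[:, 0],
                "mtt": self.params[:, 1],
                "norm": self.norms,
            }
        )


def build_dictionary(
    grid: DictionaryGrid,
    inputs: InputFunctions,
    times: np.ndarray | None = None,
) -> Dictionary:
    """Generate and L2-normalize the model curve for every grid entry.

    Exploits the model structure for speed: with DV = 1 the curve for
    (AF, MTT) is ``(AF * G_A + (1-AF) * G_P) / MTT`` where ``G_A``/``G_P``
    are the exponential convolutions of the (delay-shifted, plasma) inputs
    with rate 1/MTT, so only 2 * |MTT grid| convolutions are needed.
    """
    from .model import _shift_input, exp_conv

    if times is None:
        times = inputs.times
    times = check_times(times)
    ca, cp = inputs.plasma()
    ca = _shift_input(times, ca, inputs.tau_a)
    cp = _shift_input(times, cp, inputs.tau_p)

    k2 = 1.0 / grid.mtt_values  # (n_mtt,)
    g_a = exp_conv(times, ca, k2)  # (n_mtt, t)
    g_p = exp_conv(times, cp, k2)

    af = grid.af_values[:, None, None]  # (n_af, 1, 1)
    curves = (af * g_a[None] + (1.0 - af) * g_p[None]) * k2[None, :, None]
    # (n_af, n_mtt, t) -> columns in AF-major order
    flat = curves.reshape(-1, times.size)  # (n, t)
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        raise ValueError("dictionary entry with zero norm: input functions are all zero?")
    entries = (flat / norms[:, None]).T.copy()  # (t, n)
    return Dictionary(
        grid=grid,
        times=times,
        entries=entries,
        norms=norms,
        params=grid.param_table(),
        inputs_hash=inputs.content_hash(),
    )


@dataclass
class CompressedDictionary:
    """Rank-r randomized-SVD compression of a dictionary.

    ``left_basis`` (t x r) has orthonormal columns; ``projected`` (r x n)
    holds the dictionary in the compressed space.  Inner products between a
    projected probe and ``projected`` approximate the full inner products,
    exactly so at full rank.
    """

    source: Dictionary
    rank: int
    left_basis: np.ndarray  # (t, r)
    projected: np.ndarray  # (r, n)
    energy_retained: float


def compress(
    d: Dictionary,
    rank: int | None = None,
    energy: float = 0.99999,
    random_state: int = 0,
) -> CompressedDictionary:
    """Compress a dictionary with a seeded randomized SVD.

    If ``rank`` is None, the smallest rank retaining ``energy`` of the
    squared-singular-value energy is chosen.
    """
    t, n = d.entries.shape
    max_rank = min(t, n)
    u, s, _ = randomized_svd(
        d.entries, n_components=max_rank, random_state=random_state
    )
    cum = np.cumsum(s**2) / np.sum(s**2)
    if rank is None:
        rank = int(np.searchsorted(cum, energy) + 1)
    if not 1 <= rank <= max_rank:
        raise ValueError(f"rank must lie in [1, {max_rank}], got {rank}")
    basis = u[:, :rank]
    return CompressedDictionary(
        source=d,
        rank=rank,
        left_basis=basis,
        projected=basis.T @ d.entries,
        energy_retained=float(cum[rank - 1]),
    )


@dataclass(frozen=True)
class MatchResult:
    """Best dictionary match for one curve."""

    params: PerfusionParams | None
    inner_product: float
    column_index: int
    valid: bool = True


def match_arrays(
    curves: np.ndarray,
    d: Dictionary | CompressedDictionary,
    batch_size: int = 8192,
    clip_dv: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized exhaustive matching; returns arrays keyed by field.

    Each row of ``curves`` (m x t) is divided by its own L2 norm and scored
    against every dictionary column by inner product; the argmax column
    (ties broken by lowest column index) gives (AF, MTT) and the norm ratio
    gives DV.  Probes are processed in ``batch_size`` chunks so the m x n
    inner-product matrix never exceeds a fixed memory budget; results are
    independent of the batch size.  Zero-norm probes are flagged invalid
    (NaN parameters) rather than raising, for voxel-wise robustness.
    """
    compressed = isinstance(d, CompressedDictionary)
    src = d.source if compressed else d
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    m, t = curves.shape
    if t != src.entries.shape[0]:
        raise ValueError(
            f"curve length {t} does not match dictionary frame count {src.entries.shape[0]}"
        )
    if m == 0:
        raise ValueError("need at least one curve")

    probe_norms = np.linalg.norm(curves, axis=1)
    valid = probe_norms > 0
    idx = np.zeros(m, dtype=int)
    best_ip = np.full(m, np.nan)

    table = d.projected if compressed else src.entries  # (t or r, n)
    for start in range(0, m, batch_size):
        sl = slice(start, min(start + batch_size, m))
        block = curves[sl]
        nrm = probe_norms[sl]
        safe = np.where(nrm > 0, nrm, 1.0)
        normalized = block / safe[:, None]
        if compressed:
            normalized = normalized @ d.left_basis  # (b, r)
        ip = normalized @ table  # (b, n)
        idx[sl] = np.argmax(ip, axis=1)  # np.argmax returns the first max: lowest index
        best_ip[sl] = ip[np.arange(ip.shape[0]), idx[sl]]

    af = np.where(valid, src.params[idx, 0], np.nan)
    mtt = np.where(valid, src.params[idx, 1], np.nan)
    dv = np.where(valid, probe_norms / src.norms[idx], np.nan)
    if clip_dv:
        dv = np.clip(dv, 0.0, 1.0)
    best_ip = np.where(valid, best_ip, np.nan)
    return {
        "af": af,
        "dv": dv,
        "mtt": mtt,
        "inner_product": best_ip,
        "column": idx,
        "valid": valid,
    }


def match(
    curves: np.ndarray,
    d: Dictionary | CompressedDictionary,
    batch_size: int = 8192,
    clip_dv: bool = False,
) -> list[MatchResult]:
    """Exhaustive dictionary match; one :class:`MatchResult` per curve."""
    res = match_arrays(curves, d, batch_size=batch_size, clip_dv=clip_dv)
    out = []
    for i in range(res["af"].size):
        if res["valid"][i]:
            p = PerfusionParams(af=res["af"][i], dv=res["dv"][i], mtt=res["mtt"][i])
        else:
            p = None
        out.append(
            MatchResult(
                params=p,
                inner_product=float(res["inner_product"][i]),
                column_index=int(res["column"][i]),
                valid=bool(res["valid"][i]),
            )
        )
    return out


def estimate_dv(curve: np.ndarray, best_entry: np.ndarray) -> float:
    """DV as the L2-norm ratio of the measured curve to the model curve.

    ``best_entry`` is the *un-normalized* best-match model curve generated
    at DV = 1; because the model is linear in DV, the ratio is exact for a
    noiseless on-model curve.  Returns NaN if the entry has zero norm.
    """
    denom = float(np.linalg.norm(best_entry))
    if denom == 0.0:
        return float("nan")
    return float(np.linalg.norm(curve) / denom)


def save_dictionary(d: Dictionary, path) -> None:
    """Store a dictionary in HDF5 (entries, norms, grid axes, times)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("entries", data=d.entries)
        f.create_dataset("norms", data=d.norms)
        f.create_dataset("af_values", data=d.grid.af_values)
        f.create_dataset("mtt_values", data=d.grid.mtt_values)
        f.create_dataset("times", data=d.times)
        f.attrs["inputs_hash"] = d.inputs_hash


def load_dictionary(path) -> Dictionary:
    """Load a dictionary written by :func:`save_dictionary`."""
    import h5py

    with h5py.File(path, "r") as f:
        grid = DictionaryGrid(af_values=f["af_values"][:], mtt_values=f["mtt_values"][:])
        return Dictionary(
            grid=grid,
            times=f["times"][:],
            entries=f["entries"][:],
            norms=f["norms"][:],
            params=grid.param_table(),
            inputs_hash=f.attrs.get("inputs_hash", ""),
        )


class DictionaryMatcher(BaseEstimator):
    """Dictionary-matching perfusion estimator (scikit-learn style).

    ``fit`` builds (and optionally compresses) the dictionary from the
    configured input functions; ``predict`` maps an (m, t) array of tissue
    concentration curves to an (m, 3) array of (AF, DV, MTT) estimates.

    Parameters
    ----------
    inputs : InputFunctions
        AIF/PVIF pair used to generate the dictionary.
    times : array, optional
        Sampling grid; defaults to ``inputs.times``.
    af_step, mtt_step : float
        Grid resolution; defaults 0.01 and 1 s (AF 0–1, MTT 0.0001–100 s).
    compress_rank : int, 'auto' or None
        None: match uncompressed.  'auto': randomized-SVD rank retaining
        ``compress_energy`` of squared-singular-value energy.
    clip_dv : bool
        Clip DV estimates into [0, 1] (off by default; the raw norm ratio
        may exceed 1 for curves the model describes poorly).
    score_threshold : float
        Inner products below this are flagged invalid (0 keeps everything).
    """

    def __init__(
        self,
        inputs: InputFunctions | None = None,
        times=None,
        af_step: float = 0.01,
        mtt_step: float = 1.0,
        grid: DictionaryGrid | None = None,
        compress_rank=None,
        compress_energy: float = 0.99999,
        batch_size: int = 8192,
        clip_dv: bool = False,
        score_threshold: float = 0.0,
        random_state: int = 0,
    ):
        self.inputs = inputs
        self.times = times
        self.af_step = af_step
        self.mtt_step = mtt_step
        self.grid = grid
        self.compress_rank = compress_rank
        self.compress_energy = compress_energy
        self.batch_size = batch_size
        self.clip_dv = clip_dv
        self.score_threshold = score_threshold
        self.random_state = random_state

    def fit(self, X=None, y=None):
        """Build the dictionary.  X and y are ignored (template estimator)."""
        if self.inputs is None:
            raise ValueError("DictionaryMatcher requires `inputs` to build a dictionary")
        grid = self.grid if self.grid is not None else default_grid(self.af_step, self.mtt_step)
        self.dictionary_ = build_dictionary(grid, self.inputs, self.times)
        if self.compress_rank is not None:
            rank = None if self.compress_rank == "auto" else int(self.compress_rank)
            self.compressed_ = compress(
                self.dictionary_,
                rank=rank,
                energy=self.compress_energy,
                random_state=self.random_state,
            )
        else:
            self.compressed_ = None
        self.n_entries_ = self.dictionary_.n_entries
        return self

    def _table(self):
        return self.compressed_ if self.compressed_ is not None else self.dictionary_

    def match(self, X) -> pd.DataFrame:
        """Full match results (af, dv, mtt, inner_product, column, valid)."""
        if not hasattr(self, "dictionary_"):
            raise RuntimeError("call fit() before matching")
        res = match_arrays(
            X, self._table(), batch_size=self.batch_size, clip_dv=self.clip_dv
        )
        if self.score_threshold > 0.0:
            res["valid"] = res["valid"] & (res["inner_product"] >= self.score_threshold)
        return pd.DataFrame(res)

    def predict(self, X) -> np.ndarray:
        """(m, 3) array of (AF, DV, MTT); NaN rows for invalid curves."""
        df = self.match(X)
        out = df[["af", "dv", "mtt"]].to_numpy(float)
        out[~df["valid"].to_numpy(bool)] = np.nan
        return out

    def score_curves(self, X) -> np.ndarray:
        """Best inner product per curve (goodness of match in [-1, 1])."""
        return self.match(X)["inner_product"].to_numpy(float)
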