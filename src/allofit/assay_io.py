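"""Assay data containers, CSV readers/writers and normalization rules.

The containers hold replicate-level measurements from the functional and
binding assays used to characterize allosteric modulation of a GPCR:

* :class:`DoseResponseSeries` — single-ligand concentration–response data
  (e.g. [35S]GTPgammaS incorporation or mBRET versus agonist concentration).
* :class:`ResponseSurface` — two-ligand (orthosteric agonist x allosteric
  modulator) response surfaces, the input to the operational model of
  allosterism.
* :class:`BindingIsotherm` — one-site saturation or competition radioligand
  binding data.
* :class:`BretRecord` — raw dual-emission luminescence readings from which
  net BRET (mBRET) is derived.

Replicates are kept as raw values, never pre-averaged, so downstream fits
can weight per point; means +/- SEM are computed for display only.

Concentrations are stored in molar. Vehicle (no-ligand) rows carry a
concentration of exactly 0 together with an explicit boolean flag, so that
log-space fitting can exclude them without sentinel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseSeries",
    "ResponseSurface",
    "BindingIsotherm",
    "BretRecord",
    "SchemaError",
    "ValidationError",
    "DegenerateNormalizationError",
    "MissingControlError",
    "read_response_table",
    "write_response_table",
    "normalize_vehicle_max",
    "normalize_to_wildtype",
    "compute_mbret",
]


class SchemaError(ValueError):
    """A required column is missing or the table kind is unknown."""


class ValidationError(ValueError):
    """A row violates a container invariant (e.g. negative concentration)."""


class DegenerateNormalizationError(ValueError):
    """Reference-maximum mean does not exceed the vehicle mean."""


class MissingControlError(ValueError):
    """No control records supplied for BRET background subtraction."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSeries:
    """Replicate signals on a 1-D concentration grid, stored long-form.

    Rows are sorted by concentration ascending on construction. ``is_vehicle``
    marks no-ligand wells, which must carry concentration exactly 0.
    """

    ligand_id: str
    conc: np.ndarray  # molar, one entry per measurement row
    signal: np.ndarray  # raw counts or normalized %
    replicate: np.ndarray  # integer replicate index per row
    is_vehicle: np.ndarray  # bool per row

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.is_vehicle = np.asarray(self.is_vehicle, dtype=bool)
        n = len(self.conc)
        if not (len(self.signal) == len(self.replicate) == len(self.is_vehicle) == n):
            raise ValidationError("column lengths differ")
        if np.any(self.conc < 0):
            bad = int(np.flatnonzero(self.conc < 0)[0])
            raise ValidationError(f"negative concentration at row {bad}")
        if np.any(self.is_vehicle & (self.conc != 0.0)):
            raise ValidationError("vehicle rows must carry concentration 0")
        if np.any(~self.is_vehicle & (self.conc == 0.0)):
            raise ValidationError("zero concentration on a non-vehicle row")
        order = np.argsort(self.conc, kind="stable")
        for name in ("conc", "signal", "replicate", "is_vehicle"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def concentrations(self) -> np.ndarray:
        """Unique nonzero concentrations, ascending."""
        return np.unique(self.conc[~self.is_vehicle])

    @property
    def n_replicates(self) -> dict[float, int]:
        vals, counts = np.unique(self.conc, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def vehicle_mean(self) -> float:
        if not self.is_vehicle.any():
            raise ValidationError("no vehicle rows present")
        return float(self.signal[self.is_vehicle].mean())

    def max_conc_mean(self) -> float:
        top = self.conc[~self.is_vehicle].max()
        return float(self.signal[self.conc == top].mean())

    def mean_sem(self) -> pd.DataFrame:
        """Mean +/- SEM per concentration, for display only."""
        df = pd.DataFrame({"conc_M": self.conc, "signal": self.signal})
        g = df.groupby("conc_M")["signal"]
        return pd.DataFrame(
            {"mean": g.mean(), "sem": g.sem(), "n": g.count()}
        ).reset_index()


@dataclass
class ResponseSurface:
    """Replicate signals on a 2-D (orthosteric x allosteric) grid, long-form.

    The allosteric grid must include 0 so that a modulator-free column is
    always present.
    """

    ortho_ligand: str
    allo_ligand: str
    conc_a: np.ndarray  # molar, orthosteric
    conc_b: np.ndarray  # molar, allosteric (0 allowed and required somewhere)
    signal: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n = len(self.conc_a)
        if not (len(self.conc_b) == len(self.signal) == len(self.replicate) == n):
            raise ValidationError("column lengths differ")
        if np.any(self.conc_a < 0) or np.any(self.conc_b < 0):
            raise ValidationError("negative concentration in surface")
        if not np.any(self.conc_b == 0.0):
            raise ValidationError("surface must contain a B = 0 column")
        order = np.lexsort((self.conc_a, self.conc_b))
        for name in ("conc_a", "conc_b", "signal", "replicate"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def ortho_concentrations(self) -> np.ndarray:
        return np.unique(self.conc_a)

    @property
    def allo_concentrations(self) -> np.ndarray:
        return np.unique(self.conc_b)

    @property
    def orthosteric_only_mask(self) -> np.ndarray:
        """Rows of the modulator-free (B = 0) column."""
        return self.conc_b == 0.0

    def cell_mask(self) -> np.ndarray:
        """Boolean completeness matrix (A-levels x B-levels)."""
        a, b = self.ortho_concentrations, self.allo_concentrations
        mask = np.zeros((a.size, b.size), dtype=bool)
        ai = np.searchsorted(a, self.conc_a)
        bi = np.searchsorted(b, self.conc_b)
        mask[ai, bi] = True
        return mask

    def vehicle_mean(self) -> float:
        m = (self.conc_a == 0.0) & (self.conc_b == 0.0)
        if not m.any():
            raise ValidationError("no vehicle (A=B=0) cell present")
        return float(self.signal[m].mean())

    def max_conc_mean(self) -> float:
        """Mean signal at the highest orthosteric concentration, modulator-free."""
        col = self.orthosteric_only_mask & (self.conc_a > 0)
        top = self.conc_a[col].max()
        m = col & (self.conc_a == top)
        return float(self.signal[m].mean())


@dataclass
class BindingIsotherm:
    """One-site saturation or competition radioligand binding data.

    ``radioligand_conc`` is per-point for saturation mode and a single
    measured value (scalar) for competition mode. When a nonspecific
    reference is present, ``signal`` is taken to be nonspecific-subtracted
    specific binding.
    """

    mode: str  # "saturation" | "competition"
    radioligand_conc: np.ndarray | float
    signal: np.ndarray
    replicate: np.ndarray
    competitor_conc: np.ndarray | None = None
    radioligand_kd: float | None = None
    nonspecific_reference: np.ndarray | None = None
    is_vehicle: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("saturation", "competition"):
            raise ValidationError(f"unknown isotherm mode {self.mode!r}")
        self.signal = np.asarray(self.signal, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if self.mode == "saturation":
            self.radioligand_conc = np.asarray(self.radioligand_conc, dtype=float)
            if np.any(self.radioligand_conc < 0):
                raise ValidationError("negative radioligand concentration")
            order = np.argsort(self.radioligand_conc, kind="stable")
            self.radioligand_conc = self.radioligand_conc[order]
            self.signal = self.signal[order]
            self.replicate = self.replicate[order]
        else:
            self.radioligand_conc = float(self.radioligand_conc)
            if self.radioligand_conc <= 0:
                raise ValidationError("competition mode requires radioligand_conc > 0")
            if self.competitor_conc is None:
                raise ValidationError("competition mode requires competitor_conc")
            self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
            if np.any(self.competitor_conc < 0):
                raise ValidationError("negative competitor concentration")
            if self.is_vehicle is None:
                self.is_vehicle = self.competitor_conc == 0.0
            self.is_vehicle = np.asarray(self.is_vehicle, dtype=bool)
            order = np.argsort(self.competitor_conc, kind="stable")
            self.competitor_conc = self.competitor_conc[order]
            self.signal = self.signal[order]
            self.replicate = self.replicate[order]
            self.is_vehicle = self.is_vehicle[order]


@dataclass
class BretRecord:
    """A single dual-emission luminescence reading.

    535 nm reports the acceptor fluorophore (eYFP), 475 nm the nano-luciferase
    donor. ``is_control`` marks wells transfected without the acceptor.
    """

    emission_535: float
    emission_475: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.emission_475 <= 0:
            raise ValidationError("emission_475 must be > 0")

    @property
    def ratio(self) -> float:
        return self.emission_535 / self.emission_475


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "dose_response": {"ligand", "conc_M", "signal", "replicate"},
    "surface": {"ligand", "conc_M", "conc2_M", "signal", "replicate"},
    "saturation": {"ligand", "conc_M", "signal", "replicate"},
    "competition": {"ligand", "conc_M", "signal", "replicate"},
}


def read_response_table(
    path: Union[str, Path],
    schema: str,
    *,
    radioligand_conc: float | None = None,
    radioligand_kd: float | None = None,
) -> DoseResponseSeries | ResponseSurface | BindingIsotherm:
    """Read an assay CSV into a typed container.

    Parameters
    ----------
    path : str or Path
        Comma-separated file with a mandatory header. Concentrations in molar
        (period decimal separator).
    schema : {"dose_response", "surface", "saturation", "competition"}
        Which container to build.
    radioligand_conc, radioligand_kd : float, optional
        Competition mode metadata (molar); ``radioligand_conc`` is required
        for competition tables.

    Raises
    ------
    SchemaError
        Unknown schema label or missing required column.
    ValidationError
        Negative concentration or malformed row; the message names the
        offending 1-based data row.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown table kind {schema!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = _SCHEMAS[schema] - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")

    for col in ("conc_M", "conc2_M", "signal"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(vals.isna() & df[col].notna())
            if bad.size:
                raise ValidationError(
                    f"malformed value in column {col!r} at data row {bad[0] + 1}"
                )
            df[col] = vals
    for col in ("conc_M", "conc2_M"):
        if col in df.columns:
            neg = np.flatnonzero(df[col].to_numpy() < 0)
            if neg.size:
                raise ValidationError(
                    f"negative concentration in column {col!r} at data row {neg[0] + 1}"
                )

    if schema == "dose_response":
        ligand = str(df["ligand"].iloc[0])
        conc = df["conc_M"].to_numpy(float)
        return DoseResponseSeries(
            ligand_id=ligand,
            conc=conc,
            signal=df["signal"].to_numpy(float),
            replicate=df["replicate"].to_numpy(int),
            is_vehicle=conc == 0.0,
        )
    if schema == "surface":
        return ResponseSurface(
            ortho_ligand=str(df["ligand"].iloc[0]),
            allo_ligand=str(df["ligand2"].iloc[0]) if "ligand2" in df.columns else "modulator",
            conc_a=df["conc_M"].to_numpy(float),
            conc_b=df["conc2_M"].to_numpy(float),
            signal=df["signal"].to_numpy(float),
            replicate=df["replicate"].to_numpy(int),
        )
    if schema == "saturation":
        return BindingIsotherm(
            mode="saturation",
            radioligand_conc=df["conc_M"].to_numpy(float),
            signal=df["signal"].to_numpy(float),
            replicate=df["replicate"].to_numpy(int),
        )
    # competition
    if radioligand_conc is None:
        raise SchemaError("competition tables require radioligand_conc")
    return BindingIsotherm(
        mode="competition",
        radioligand_conc=radioligand_conc,
        competitor_conc=df["conc_M"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        replicate=df["replicate"].to_numpy(int),
        radioligand_kd=radioligand_kd,
    )


def write_response_table(obj, path: Union[str, Path]) -> None:
    """Write a container back to the CSV dialect :func:`read_response_table` accepts.

    Round-tripping reproduces values bit-identically on the same platform
    (floats are serialized with `repr` precision).
    """
    if isinstance(obj, DoseResponseSeries):
        df = pd.DataFrame(
            {
                "ligand": obj.ligand_id,
                "conc_M": obj.conc,
                "signal": obj.signal,
                "replicate": obj.replicate,
            }
        )
    elif isinstance(obj, ResponseSurface):
        df = pd.DataFrame(
            {
                "ligand": obj.ortho_ligand,
                "ligand2": obj.allo_ligand,
                "conc_M": obj.conc_a,
                "conc2_M": obj.conc_b,
                "signal": obj.signal,
                "replicate": obj.replicate,
            }
        )
    elif isinstance(obj, BindingIsotherm):
        conc = (
            obj.radioligand_conc
            if obj.mode == "saturation"
            else obj.competitor_conc
        )
        df = pd.DataFrame(
            {
                "ligand": "radioligand" if obj.mode == "saturation" else "competitor",
                "conc_M": conc,
                "signal": obj.signal,
                "replicate": obj.replicate,
            }
        )
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    # %.17g guarantees float64 round-trip through text
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _affine_percent(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise DegenerateNormalizationError(
            f"reference-max mean ({hi}) must exceed vehicle mean ({lo})"
        )
    return 100.0 * (x - lo) / (hi - lo)


def normalize_vehicle_max(obj, reference_ligand: str | None = None):
    """Rescale signals so vehicle maps to 0% and the reference maximum to 100%.

    The reference is the mean signal at the highest concentration of the
    orthosteric/reference ligand (for a surface, the modulator-free column).
    Returns a new container of the same shape on the % scale. The map is
    affine, hence order-preserving.
    """
    if isinstance(obj, DoseResponseSeries):
        if reference_ligand is not None and reference_ligand != obj.ligand_id:
            raise ValidationError(
                f"reference ligand {reference_ligand!r} not in series {obj.ligand_id!r}"
            )
        lo, hi = obj.vehicle_mean(), obj.max_conc_mean()
        return DoseResponseSeries(
            ligand_id=obj.ligand_id,
            conc=obj.conc.copy(),
            signal=_affine_percent(obj.signal, lo, hi),
            replicate=obj.replicate.copy(),
            is_vehicle=obj.is_vehicle.copy(),
        )
    if isinstance(obj, ResponseSurface):
        lo, hi = obj.vehicle_mean(), obj.max_conc_mean()
        return ResponseSurface(
            ortho_ligand=obj.ortho_ligand,
            allo_ligand=obj.allo_ligand,
            conc_a=obj.conc_a.copy(),
            conc_b=obj.conc_b.copy(),
            signal=_affine_percent(obj.signal, lo, hi),
            replicate=obj.replicate.copy(),
        )
    raise TypeError(f"cannot normalize {type(obj).__name__}")


def normalize_to_wildtype(
    mutant: DoseResponseSeries,
    wt_vehicle_mean: float,
    wt_refmax_mean: float,
) -> DoseResponseSeries:
    """Express a mutant series on the paired wild-type percent scale.

    Same affine map as :func:`normalize_vehicle_max` but anchored on the
    wild-type vehicle and reference-maximum means, so mutant maxima may
    exceed 100% or fall below (e.g. a mutant expressed at 20% of wild type
    tops out near 20% on this scale).
    """
    return DoseResponseSeries(
        ligand_id=mutant.ligand_id,
        conc=mutant.conc.copy(),
        signal=_affine_percent(mutant.signal, wt_vehicle_mean, wt_refmax_mean),
        replicate=mutant.replicate.copy(),
        is_vehicle=mutant.is_vehicle.copy(),
    )


def compute_mbret(
    samples: Sequence[BretRecord], controls: Sequence[BretRecord]
) -> np.ndarray:
    """Net BRET in milli-units: (sample ratio − mean control ratio) × 1000.

    The control ratio (cells without the acceptor fluorophore) is averaged
    per experiment and subtracted as a single background term. The result is
    invariant to rescaling both emission channels of every record by a
    common factor.
    """
    controls = list(controls)
    if not controls:
        raise MissingControlError("compute_mbret requires at least one control record")
    bg = float(np.mean([c.ratio for c in controls]))
    return np.array([(s.ratio - bg) * 1000.0 for s in samples])
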