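"""SIFT-MS selected-ion-mode quantification.

Selected ion flow tube mass spectrometry (SIFT-MS) quantifies trace VOCs by
chemical ionization: a selected reagent ion (H3O+, NO+ or O2+) reacts with the
analyte at a known rate coefficient, and the analyte number density follows
from first-order kinetics on the measured precursor and product count rates:

    [A] = R_product / (R_precursor * k_eff * t_reaction)

with ``k_eff = rate_coefficient * branching_fraction``.  Dividing by the
carrier-gas number density and scaling by 1e9 converts to ppb (by volume).

A compound is typically monitored on several product-ion channels; channels
shared with other compounds (isobaric interference) report inflated
concentrations.  The instrument's "tolerance feature" handles this by taking
the lowest per-channel estimate and averaging it with every estimate within a
fractional tolerance band (20% by default); channels beyond the band are
discarded.  Compounds whose every channel is interfered carry a ``relative``
scale flag through the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REAGENT_IONS = ("H3O+", "NO+", "O2+")
CATEGORIES = ("alkanes", "ketones", "aldehydes", "alcohols", "amines", "thiols", "others")

#: metadata columns of the wide sample table, everything else is a VOC column
META_COLS = ("sample_id", "subject_id", "group", "site", "type")


class InvalidInputError(ValueError):
    """A value violated a type invariant; the message names the field."""


class SchemaError(ValueError):
    """A record referenced an unknown channel / label or a header mismatched."""


class DuplicateRecordError(ValueError):
    """Two scans were supplied for one (sample, channel)."""


@dataclass(frozen=True)
class ProductIonChannel:
    """One quantification channel of a compound.

    (reagent, product_mz) pairs may repeat across compounds — that is exactly
    the interference the tolerance rule deals with — but must be unique within
    one compound.
    """

    compound_id: str
    reagent: str
    product_mz: int
    rate_coefficient: float  # reaction rate k, cm^3 s^-1
    branching_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.reagent not in REAGENT_IONS:
            raise InvalidInputError(f"reagent must be one of {REAGENT_IONS}, got {self.reagent!r}")
        if not self.rate_coefficient > 0:
            raise InvalidInputError("rate_coefficient must be > 0")
        if not (0 < self.branching_fraction <= 1):
            raise InvalidInputError("branching_fraction must be in (0, 1]")

    @property
    def key(self) -> tuple[str, int]:
        return (self.reagent, self.product_mz)


@dataclass(frozen=True)
class CompoundSpec:
    compound_id: str
    name: str
    category: str
    channels: tuple[ProductIonChannel, ...]
    scale: str = "absolute"  # "absolute" | "relative"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if not self.channels:
            raise InvalidInputError("channels must be non-empty")
        if self.scale not in ("absolute", "relative"):
            raise InvalidInputError("scale must be 'absolute' or 'relative'")
        keys = [ch.key for ch in self.channels]
        if len(set(keys)) != len(keys):
            raise InvalidInputError(f"duplicate (reagent, product_mz) within compound {self.compound_id}")


@dataclass(frozen=True)
class InstrumentParams:
    """Kinetic constants of the instrument configuration.

    reaction_time in seconds, dilution_factor dimensionless, carrier gas
    number density in molecules cm^-3 (2.46e19 at 1 atm / 298 K).
    """

    reaction_time: float = 5e-3
    dilution_factor: float = 1.0
    carrier_number_density: float = 2.46e19

    def __post_init__(self) -> None:
        for name in ("reaction_time", "dilution_factor", "carrier_number_density"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")


@dataclass(frozen=True)
class IonScanRecord:
    sample_id: str
    channel: ProductIonChannel
    product_rate: float  # counts s^-1
    precursor_rate: float  # counts s^-1

    def __post_init__(self) -> None:
        if not self.precursor_rate > 0:
            raise InvalidInputError("precursor_rate must be > 0")
        if self.product_rate < 0:
            raise InvalidInputError("product_rate must be >= 0")


@dataclass
class QuantResult:
    sample_id: str
    compound_id: str
    channel_estimates: list[tuple[ProductIonChannel, float]]
    accepted_channels: list[tuple[ProductIonChannel, float]]
    consensus_ppb: float
    scale: str = "absolute"


def channel_concentration(scan: IonScanRecord, instr: InstrumentParams) -> float:
    """Concentration (ppb) from one channel via first-order SIFT-MS kinetics.

    Linear in product_rate, inversely linear in precursor_rate.
    """
    k_eff = scan.channel.rate_coefficient * scan.channel.branching_fraction
    number_density = scan.product_rate / (scan.precursor_rate * k_eff * instr.reaction_time)
    return number_density * instr.dilution_factor / instr.carrier_number_density * 1e9


def tolerance_consensus(
    estimates: Sequence[float], tolerance: float = 0.20
) -> tuple[float, list[float]]:
    """Consensus concentration from per-channel estimates.

    Accepts the lowest estimate and everything within ``tolerance`` of it
    (boundary inclusive: c <= c_min * (1 + tolerance)) and returns their
    unweighted mean together with the accepted estimates.
    """
    if len(estimates) == 0:
        raise InvalidInputError("estimates must be non-empty")
    est = [float(e) for e in estimates]
    if any(e < 0 for e in est):
        raise InvalidInputError("estimates must be >= 0")
    c_min = min(est)
    accepted = [e for e in est if e <= c_min * (1.0 + tolerance)]
    return float(np.mean(accepted)), accepted


def quantify_sample(
    scans: Iterable[IonScanRecord],
    library: Sequence[CompoundSpec],
    instr: InstrumentParams,
    tolerance: float = 0.20,
) -> tuple[dict[str, float], dict[str, QuantResult]]:
    """Quantify every library compound in one sample.

    Returns ``(row, details)`` where ``row`` maps compound_id -> consensus ppb
    (NaN when the sample has no scan on any of the compound's channels —
    missing, not zero) and ``details`` carries accepted channel sets per
    compound for provenance.
    """
    scans = list(scans)
    sample_ids = {s.sample_id for s in scans}
    if len(sample_ids) > 1:
        raise InvalidInputError(f"scans span multiple samples: {sorted(sample_ids)}")

    known = {(ch.compound_id, ch.key) for spec in library for ch in spec.channels}
    by_channel: dict[tuple[str, tuple[str, int]], IonScanRecord] = {}
    for s in scans:
        ck = (s.channel.compound_id, s.channel.key)
        if ck not in known:
            raise SchemaError(f"scan references unknown channel {ck}")
        if ck in by_channel:
            raise DuplicateRecordError(f"duplicate scan for channel {ck}")
        by_channel[ck] = s

    row: dict[str, float] = {}
    details: dict[str, QuantResult] = {}
    sample_id = next(iter(sample_ids)) if sample_ids else ""
    for spec in library:
        ests: list[tuple[ProductIonChannel, float]] = []
        for ch in spec.channels:
            scan = by_channel.get((spec.compound_id, ch.key))
            if scan is not None:
                ests.append((ch, channel_concentration(scan, instr)))
        if not ests:
            row[spec.compound_id] = float("nan")
            continue
        consensus, accepted_vals = tolerance_consensus([e for _, e in ests], tolerance)
        # match accepted values back to channels (multiset semantics)
        pool = list(accepted_vals)
        accepted = []
        for ch, e in ests:
            if e in pool:
                accepted.append((ch, e))
                pool.remove(e)
        row[spec.compound_id] = consensus
        details[spec.compound_id] = QuantResult(
            sample_id, spec.compound_id, ests, accepted, consensus, spec.scale
        )
    return row, details


def stability_check(
    replicates: pd.DataFrame | Mapping[str, Sequence[float]],
    cv_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-VOC coefficient of variation over repeated measurements.

    ``replicates``: columns = VOCs, rows = replicate measurements (>= 2).
    CV = sample sd (ddof=1) / mean, defined 0 when sd and mean are both 0.
    A VOC is flagged stable iff CV <= cv_threshold.
    """
    df = pd.DataFrame(replicates)
    if len(df) < 2:
        raise InvalidInputError("stability_check needs >= 2 replicates per VOC")
    if (df.to_numpy() < 0).any():
        raise InvalidInputError("replicate values must be >= 0")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    cv = pd.Series(np.zeros(len(mean)), index=mean.index, dtype=float)
    nonzero = ~((mean == 0) & (sd == 0))
    cv[nonzero] = sd[nonzero] / mean[nonzero]
    return pd.DataFrame({"cv": cv, "stable": cv <= cv_threshold})


# ---------------------------------------------------------------------------
# on-disk schemas

SCAN_COLUMNS = ["sample_id", "reagent", "product_mz", "product_rate", "precursor_rate"]
LIBRARY_COLUMNS = [
    "compound_id", "name", "category", "reagent", "product_mz",
    "rate_coefficient", "branching_fraction", "scale",
]


def read_library(path: str | Path) -> list[CompoundSpec]:
    """Read a compound library CSV (one row per channel)."""
    df = pd.read_csv(path)
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"library missing columns: {sorted(missing)}")
    specs = []
    for cid, grp in df.groupby("compound_id", sort=False):
        channels = tuple(
            ProductIonChannel(
                compound_id=str(cid),
                reagent=r.reagent,
                product_mz=int(r.product_mz),
                rate_coefficient=float(r.rate_coefficient),
                branching_fraction=float(r.branching_fraction),
            )
            for r in grp.itertuples()
        )
        first = grp.iloc[0]
        specs.append(
            CompoundSpec(str(cid), str(first["name"]), str(first["category"]), channels, str(first["scale"]))
        )
    return specs


def read_scans(path: str | Path, library: Sequence[CompoundSpec]) -> list[IonScanRecord]:
    """Read long-format ion scans, resolving channels against the library.

    A (reagent, product_mz) shared by several compounds yields one scan per
    owning compound: the full count rate contributes to each compound's
    estimate independently and the tolerance rule discards the inflated ones.
    """
    df = pd.read_csv(path)
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"scan table missing columns: {sorted(missing)}")
    by_key: dict[tuple[str, int], list[ProductIonChannel]] = {}
    for spec in library:
        for ch in spec.channels:
            by_key.setdefault(ch.key, []).append(ch)
    records: list[IonScanRecord] = []
    for r in df.itertuples():
        key = (str(r.reagent), int(r.product_mz))
        owners = by_key.get(key)
        if not owners:
            raise SchemaError(f"scan references unknown channel {key}")
        for ch in owners:
            records.append(IonScanRecord(str(r.sample_id), ch, float(r.product_rate), float(r.precursor_rate)))
    return records


def quantify_table(
    scans: Sequence[IonScanRecord],
    library: Sequence[CompoundSpec],
    instr: InstrumentParams,
    tolerance: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Quantify many samples into a wide table (rows = samples, cols = compounds).

    Also returns a JSON-ready side-car mapping sample -> compound -> accepted
    channel descriptors.
    """
    by_sample: dict[str, list[IonScanRecord]] = {}
    for s in scans:
        by_sample.setdefault(s.sample_id, []).append(s)
    rows, sidecar = {}, {}
    for sid, ss in by_sample.items():
        row, details = quantify_sample(ss, library, instr, tolerance)
        rows[sid] = row
        sidecar[sid] = {
            cid: {
                "consensus_ppb": q.consensus_ppb,
                "scale": q.scale,
                "accepted": [f"{ch.reagent}@{ch.product_mz}" for ch, _ in q.accepted_channels],
            }
            for cid, q in details.items()
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table, sidecar


def write_quant_outputs(table: pd.DataFrame, sidecar: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "concentrations.tsv", sep="\t", na_rep="NA", float_format="%.10g")
    (out / "accepted_channels.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def placeholder_library(n_compounds: int = 6, seed: int = 0) -> list[CompoundSpec]:
    """A small illustrative compound panel (not a reconstruction of any
    instrument's real method file)."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_compounds):
        cid = f"voc_{i + 1:03d}"
        n_ch = int(rng.integers(1, 4))
        channels = tuple(
            ProductIonChannel(
                compound_id=cid,
                reagent=REAGENT_IONS[int(rng.integers(0, 3))],
                product_mz=int(30 + i * 7 + j),
                rate_coefficient=float(rng.uniform(1e-9, 4e-9)),
                branching_fraction=float(rng.uniform(0.5, 1.0)),
            )
            for j in range(n_ch)
        )
        specs.append(
            CompoundSpec(cid, f"compound-{i + 1}", CATEGORIES[i % len(CATEGORIES)], channels,
                         "relative" if i == n_compounds - 1 else "absolute")
        )
    return specs
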