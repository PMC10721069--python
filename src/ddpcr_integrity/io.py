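"""Plate CSV input/output in a QuantaSoft-style dialect.

Droplet-reader exports carry two rows per well, one per target/channel,
each repeating the well's four category droplet counts and accepted
droplet total.  Exact column labels vary by software version, so the
reader is keyed on *logical* fields mapped to concrete column labels by
a configurable dialect (the default dialect is the one this package's
simulator writes).

``append_integrity`` reproduces the published analysis app's output
contract: the chosen model's integrity value is appended identically to
both rows of each well (``NA`` when the model is inapplicable), together
with a Boolean column verifying that the duplicated values are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import pandas as pd
import yaml

from . import models
from .models import DropletCounts, IntegrityResult
from .simulate import MixtureDesign, SimulatedWell

__all__ = [
    "PARSER_VERSION",
    "DEFAULT_DIALECT",
    "REQUIRED_FIELDS",
    "DialectError",
    "StructureError",
    "WellRecord",
    "PlateTable",
    "estimate_integrity",
    "read_plate_csv",
    "write_plate_csv",
    "write_results_csv",
    "append_integrity",
    "plate_from_wells",
    "dialect_from_yaml",
]

PARSER_VERSION = "1.0"

#: Logical field -> column label.  Optional fields may be absent from a file.
DEFAULT_DIALECT: dict[str, str] = {
    "well": "Well",
    "sample": "Sample",
    "target": "Target",
    "channel": "Channel",
    "concentration": "Concentration",
    "n_double": "Ch1+Ch2+",
    "n_t1_only": "Ch1+Ch2-",
    "n_t2_only": "Ch1-Ch2+",
    "n_negative": "Ch1-Ch2-",
    "accepted": "AcceptedDroplets",
    "linkage": "Linkage",
    "replicate": "Replicate",
    "dilution": "Dilution",
}

REQUIRED_FIELDS = (
    "well",
    "target",
    "n_double",
    "n_t1_only",
    "n_t2_only",
    "n_negative",
    "accepted",
)

# Annotation column labels (the published app's columns M and N are
# positional; this implementation names them).
INTEGRITY_COL = "IntegrityPercent"
INTEGRITY_EXACT_COL = "IntegrityPercentExact"
NA_REASON_COL = "NAReason"
CONSISTENT_COL = "RowsConsistent"


class DialectError(ValueError):
    """A required logical column is missing from the file or dialect."""


class StructureError(ValueError):
    """Well rows are malformed (odd row count, disagreeing duplicates)."""


@dataclass(frozen=True)
class WellRecord:
    """One export row: a (well, target/channel) pair with the well's
    category counts repeated."""

    well: str
    target: str
    channel: Optional[int]
    concentration: Optional[float]
    counts: DropletCounts
    accepted: int
    linkage: Optional[float] = None
    sample: Optional[str] = None


@dataclass(frozen=True)
class PlateTable:
    """Ordered two-rows-per-well table plus its dialect and provenance."""

    df: pd.DataFrame
    dialect: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIALECT))
    provenance: str = f"in-memory (parser v{PARSER_VERSION})"

    def col(self, logical: str) -> str:
        try:
            return self.dialect[logical]
        except KeyError:
            raise DialectError(f"dialect does not map logical field '{logical}'")

    @property
    def n_wells(self) -> int:
        return self.df[self.col("well")].nunique() if len(self.df) else 0

    def records(self) -> Iterator[WellRecord]:
        c = self.col
        has = lambda f: f in self.dialect and self.dialect[f] in self.df.columns
        for _, row in self.df.iterrows():
            yield WellRecord(
                well=str(row[c("well")]),
                target=str(row[c("target")]),
                channel=int(row[c("channel")]) if has("channel") else None,
                concentration=(
                    float(row[c("concentration")])
                    if has("concentration") and pd.notna(row[c("concentration")])
                    else None
                ),
                counts=DropletCounts(
                    int(row[c("n_double")]),
                    int(row[c("n_t1_only")]),
                    int(row[c("n_t2_only")]),
                    int(row[c("n_negative")]),
                ),
                accepted=int(row[c("accepted")]),
                linkage=(
                    float(row[c("linkage")])
                    if has("linkage") and pd.notna(row[c("linkage")])
                    else None
                ),
                sample=str(row[c("sample")]) if has("sample") else None,
            )

    def well_counts(self) -> Iterator[tuple[str, dict, DropletCounts]]:
        """Yield one ``(well_id, metadata, DropletCounts)`` per well.

        Metadata holds sample/replicate/dilution when those optional
        dialect columns are present.
        """
        c = self.col
        for well_id, grp in self.df.groupby(c("well"), sort=False):
            row = grp.iloc[0]
            meta = {}
            for f in ("sample", "replicate", "dilution"):
                label = self.dialect.get(f)
                if label in grp.columns:
                    meta[f] = row[label]
            counts = DropletCounts(
                int(row[c("n_double")]),
                int(row[c("n_t1_only")]),
                int(row[c("n_t2_only")]),
                int(row[c("n_negative")]),
            )
            yield str(well_id), meta, counts

    def equals(self, other: "PlateTable") -> bool:
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True),
                other.df.reset_index(drop=True),
                check_dtype=False,
                check_exact=False,
                rtol=1e-12,
                atol=1e-12,
            )
        except AssertionError:
            return False
        return True


def _validate_plate(df: pd.DataFrame, dialect: dict[str, str], source: str) -> None:
    for logical in REQUIRED_FIELDS:
        if logical not in dialect:
            raise DialectError(f"dialect does not map required field '{logical}'")
        if dialect[logical] not in df.columns:
            raise DialectError(
                f"missing required column '{dialect[logical]}' "
                f"(logical field '{logical}') in {source}"
            )
    problems: list[str] = []
    count_cols = [dialect[f] for f in ("n_double", "n_t1_only", "n_t2_only", "n_negative")]
    acc_col = dialect["accepted"]
    for well_id, grp in df.groupby(dialect["well"], sort=False):
        if len(grp) != 2:
            problems.append(f"well {well_id}: expected 2 rows, found {len(grp)}")
            continue
        for col in count_cols + [acc_col]:
            vals = grp[col].to_numpy()
            if vals[0] != vals[1]:
                problems.append(
                    f"well {well_id}: rows disagree on '{col}' ({vals[0]} vs {vals[1]})"
                )
        total = int(grp.iloc[0][count_cols].sum())
        if total != int(grp.iloc[0][acc_col]):
            problems.append(
                f"well {well_id}: category counts sum to {total} but "
                f"'{acc_col}' is {int(grp.iloc[0][acc_col])}"
            )
    if problems:
        raise StructureError("; ".join(problems))


def read_plate_csv(path, dialect: Optional[dict[str, str]] = None) -> PlateTable:
    """Read and validate a plate export.

    Raises :class:`DialectError` naming any missing required column and
    :class:`StructureError` naming every malformed well (wells are never
    silently dropped).
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path)
    _validate_plate(df, dialect, str(path))
    return PlateTable(
        df=df, dialect=dialect, provenance=f"{path} (parser v{PARSER_VERSION})"
    )


def write_plate_csv(plate: PlateTable, path) -> None:
    """Write a plate as RFC-4180 CSV with deterministic column order."""
    plate.df.to_csv(path, index=False)


#: Results files use the same CSV writer; the annotation columns simply ride
#: along at the end of the row.
write_results_csv = write_plate_csv


def estimate_integrity(
    counts: DropletCounts,
    method: str,
    k_max: int = models.DEFAULT_K_MAX,
    na_rule: str = "strict",
    droplet_volume_nl: float = models.DEFAULT_DROPLET_VOLUME_NL,
    use_concentration: bool = False,
) -> IntegrityResult:
    """Dispatch to one of the four integrity models by name; model
    errors (saturation, infeasible fractions) become NA results with the
    error message as the reason code."""
    try:
        if method == "simple":
            return models.integrity_simple(counts, use_concentration=use_concentration)
        if method == "linkage_avg":
            return models.integrity_linkage_avg(counts, droplet_volume_nl)
        if method == "linkage_comp":
            return models.integrity_linkage_comp(counts, droplet_volume_nl)
        if method == "poisson_multinomial":
            return models.integrity_poisson_multinomial(counts, k_max=k_max, na_rule=na_rule)
    except (models.SaturationError, models.InfeasibleFractionError) as exc:
        return IntegrityResult.na(method, str(exc))
    raise ValueError(f"unknown method {method!r}")


def append_integrity(
    plate: PlateTable,
    method: str = "poisson_multinomial",
    k_max: int = models.DEFAULT_K_MAX,
    na_rule: str = "strict",
    droplet_volume_nl: float = models.DEFAULT_DROPLET_VOLUME_NL,
    use_concentration: bool = False,
) -> PlateTable:
    """Annotate every well with one model's integrity estimate.

    The value is written identically to both rows of the well: a
    presentation column rounded to 1 decimal place (or ``NA``), a
    full-precision companion column, an NA reason column, and a Boolean
    column that is true iff the two duplicated values are bit-identical.
    """
    df = plate.df.copy()
    well_col = plate.col("well")
    pres = pd.Series("NA", index=df.index, dtype=object)
    exact = pd.Series(math.nan, index=df.index, dtype=float)
    reason = pd.Series("", index=df.index, dtype=object)
    for well_id, meta, counts in plate.well_counts():
        res = estimate_integrity(
            counts,
            method,
            k_max=k_max,
            na_rule=na_rule,
            droplet_volume_nl=droplet_volume_nl,
            use_concentration=use_concentration,
        )
        mask = df[well_col] == well_id
        if res.is_na:
            pres[mask] = "NA"
            reason[mask] = res.na_reason or ""
        else:
            pres[mask] = f"{res.integrity_percent:.1f}"
            exact[mask] = res.integrity_percent
    df[INTEGRITY_COL] = pres
    df[INTEGRITY_EXACT_COL] = exact
    df[NA_REASON_COL] = reason
    consistent = []
    for _, grp in df.groupby(well_col, sort=False):
        vals = grp[INTEGRITY_COL].tolist()
        exacts = grp[INTEGRITY_EXACT_COL].tolist()
        same_exact = all(
            (math.isnan(e) and math.isnan(exacts[0]))
            or (not math.isnan(e) and e == exacts[0])
            for e in exacts
        )
        ok = all(v == vals[0] for v in vals) and same_exact
        consistent.extend([ok] * len(grp))
    df[CONSISTENT_COL] = consistent
    return PlateTable(df=df, dialect=plate.dialect, provenance=plate.provenance)


def plate_from_wells(
    wells: list[SimulatedWell],
    design: Optional[MixtureDesign] = None,
    targets: tuple[str, str] = ("CMV", "polyA"),
    dialect: Optional[dict[str, str]] = None,
) -> PlateTable:
    """Assemble simulated wells into a two-rows-per-well plate table.

    Well ids are plate coordinates ``P<plate>-<row><col>`` over
    consecutive 96-well (8x12) plates.  Per-channel concentrations and
    the linkage concentration are reported where the Poisson correction
    is defined, mirroring an instrument export.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    v_nl = design.droplet_volume_nl if design else models.DEFAULT_DROPLET_VOLUME_NL
    rows = []
    for i, w in enumerate(wells):
        plate_no, pos = divmod(i, 96)
        coord = f"{'ABCDEFGH'[pos // 12]}{pos % 12 + 1:02d}"
        well_id = f"P{plate_no + 1}-{coord}"
        c = w.counts
        try:
            lam1, lam2, lam_tot = models.target_lambdas(c)
            conc = (
                models.lambda_to_copies_per_ul(lam1, v_nl),
                models.lambda_to_copies_per_ul(lam2, v_nl),
            )
            linkage = models.lambda_to_copies_per_ul(lam1 + lam2 - lam_tot, v_nl)
        except models.SaturationError:
            conc = (math.nan, math.nan)
            linkage = math.nan
        for ch, (target, target_conc) in enumerate(zip(targets, conc), start=1):
            rows.append(
                {
                    dialect["well"]: well_id,
                    dialect["sample"]: w.sample,
                    dialect["target"]: target,
                    dialect["channel"]: ch,
                    dialect["concentration"]: target_conc,
                    dialect["n_double"]: c.n_double,
                    dialect["n_t1_only"]: c.n_t1_only,
                    dialect["n_t2_only"]: c.n_t2_only,
                    dialect["n_negative"]: c.n_negative,
                    dialect["accepted"]: int(c.d_total),
                    dialect["linkage"]: linkage,
                    dialect["replicate"]: w.replicate,
                    dialect["dilution"]: w.dilution_copies_per_ul,
                }
            )
    columns = [dialect[f] for f in DEFAULT_DIALECT]
    df = pd.DataFrame(rows, columns=columns)
    return PlateTable(
        df=df, dialect=dialect, provenance=f"simulated (parser v{PARSER_VERSION})"
    )


def dialect_from_yaml(path) -> dict[str, str]:
    """Load a logical-field -> column-label map from a YAML file; fields
    not mentioned fall back to the default dialect."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    dialect = dict(DEFAULT_DIALECT)
    dialect.update({str(k): str(v) for k, v in user.items()})
    return dialect
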