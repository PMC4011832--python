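"""Domain types, file I/O and packaged fixtures for TLDA Cq analysis.

The raw substrate of every analysis stage is a :class:`CqMatrix` — a
rectangular sample × assay grid of quantification-cycle values in which
non-amplifying wells carry a distinct UNDETERMINED sentinel (represented
as NaN).  The sentinel is preserved losslessly through I/O; substitution
by a fixed cycle number happens only inside the normalization stage.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNDETERMINED",
    "DEFAULT_UNDETERMINED_TOKENS",
    "Role",
    "OrClass",
    "Smoking",
    "Assay",
    "AssayPanel",
    "CqMatrix",
    "SampleRecord",
    "FormatError",
    "CqParseError",
    "PanelValidationError",
    "read_cq_table",
    "write_cq_table",
    "read_assay_panel",
    "write_assay_panel",
    "load_default_panel",
    "load_table2_fixture",
    "load_cohort_metadata",
    "read_sample_table",
]

#: Sentinel for wells whose amplification never crossed the threshold.
UNDETERMINED = float("nan")

DEFAULT_UNDETERMINED_TOKENS = ("Undetermined", "NA", "")

DEFAULT_MAX_CYCLES = 40.0


class FormatError(ValueError):
    """A file does not have the structure the reader expects."""


class CqParseError(ValueError):
    """A Cq cell is neither numeric nor a recognised undetermined token."""


class PanelValidationError(ValueError):
    """An assay panel violates a structural invariant."""


class Role(str, enum.Enum):
    OR_TARGET = "or_target"
    ENDOGENOUS_REF = "endogenous_ref"
    OE_REF = "oe_ref"
    INTERNAL_CONTROL = "internal_control"


class OrClass(str, enum.Enum):
    CLASS_I = "class_I"
    CLASS_II = "class_II"
    NOT_APPLICABLE = "not_applicable"


class Smoking(str, enum.Enum):
    NEVER = "never"
    PAST = "past"
    CURRENT = "current"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Assay:
    """One well-level assay on the low-density array.

    ``intron_spanning`` assays are expected to stay undetermined on
    genomic DNA; by convention their ``assay_id`` carries an ``_m``
    suffix.  ``or_class`` is meaningful for OR targets only.
    """

    assay_id: str
    gene_symbol: str
    role: Role
    or_class: OrClass = OrClass.NOT_APPLICABLE
    deorphanized: bool = False
    agonist: str = ""
    potentially_nonfunctional: bool = False
    intron_spanning: bool = False

    def __post_init__(self) -> None:
        if self.role is Role.OR_TARGET:
            if self.or_class is OrClass.NOT_APPLICABLE:
                raise PanelValidationError(
                    f"{self.assay_id}: OR target requires class_I or class_II"
                )
        elif self.or_class is not OrClass.NOT_APPLICABLE:
            raise PanelValidationError(
                f"{self.assay_id}: or_class only applies to OR targets"
            )


@dataclass
class AssayPanel:
    """Ordered collection of assays with uniqueness and role accounting."""

    assays: list[Assay]

    def __post_init__(self) -> None:
        ids = [a.assay_id for a in self.assays]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate assay_id: {sorted(dupes)}")
        self._by_id = {a.assay_id: a for a in self.assays}

    def __len__(self) -> int:
        return len(self.assays)

    def __getitem__(self, assay_id: str) -> Assay:
        return self._by_id[assay_id]

    def __contains__(self, assay_id: str) -> bool:
        return assay_id in self._by_id

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {r.value: 0 for r in Role}
        for a in self.assays:
            counts[a.role.value] += 1
        return counts

    def by_role(self, role: Role | str) -> list[Assay]:
        role = Role(role)
        return [a for a in self.assays if a.role is role]

    def or_assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays if a.role is Role.OR_TARGET]

    def gene_to_assay(self) -> dict[str, str]:
        return {a.gene_symbol: a.assay_id for a in self.assays}


@dataclass
class CqMatrix:
    """Sample × assay grid of Cq values with per-sample run/condition tags.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id with assay_id columns; NaN encodes
        the UNDETERMINED sentinel.
    run_id
        Run label per sample (non-empty strings).
    condition
        Free-form condition tag per sample (``rt_plus``, ``rt_minus``,
        ``gdna``, ``plasmid``, ``whom``, ``inferior_turbinate``, ...).
    """

    values: pd.DataFrame
    run_id: pd.Series
    condition: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.run_id = pd.Series(self.run_id, dtype=str).reindex(self.values.index)
        self.condition = pd.Series(self.condition, dtype=str).reindex(self.values.index)
        if self.run_id.isna().any() or (self.run_id == "").any():
            raise FormatError("every sample needs a non-empty run_id")
        finite = self.values.to_numpy()
        bad = finite[np.isfinite(finite) & ((finite <= 0) | (finite > DEFAULT_MAX_CYCLES))]
        if bad.size:
            raise FormatError(
                f"numeric Cq values must be in (0, {DEFAULT_MAX_CYCLES}]; got {bad[:5]}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    def n_undetermined(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_assays(self, assay_ids: Sequence[str]) -> "CqMatrix":
        return CqMatrix(self.values.loc[:, list(assay_ids)].copy(),
                        self.run_id.copy(), self.condition.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CqMatrix":
        idx = list(sample_ids)
        return CqMatrix(self.values.loc[idx].copy(),
                        self.run_id.loc[idx].copy(), self.condition.loc[idx].copy())

    def equals(self, other: "CqMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.run_id.equals(other.run_id)
            and self.condition.equals(other.condition)
        )


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one donor (structure of the cohort table)."""

    sample_id: str
    age: float
    sex: str
    rin: float
    smoking: Smoking
    delay_hours: float
    origin: str = ""
    cause_of_death: str = ""

    def __post_init__(self) -> None:
        if not (1.0 <= self.rin <= 10.0):
            raise ValueError(f"{self.sample_id}: RIN {self.rin} outside [1, 10]")
        if self.age <= 0:
            raise ValueError(f"{self.sample_id}: age must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.sample_id}: sex must be F or M")


# ---------------------------------------------------------------------------
# Cq table I/O
# ---------------------------------------------------------------------------

def _parse_cq_cell(raw, tokens: tuple[str, ...], where: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNDETERMINED
    s = str(raw).strip()
    if s in tokens:
        return UNDETERMINED
    try:
        return float(s)
    except ValueError:
        raise CqParseError(f"cannot parse Cq value {s!r} at {where}") from None


def read_cq_table(
    path,
    dialect: str = "auto",
    sep: str | None = None,
    undetermined_tokens: Iterable[str] = DEFAULT_UNDETERMINED_TOKENS,
    default_run_id: str = "run1",
    default_condition: str = "rt_plus",
) -> CqMatrix:
    """Read a Cq matrix from a wide or long delimited text file.

    Long format has columns ``sample_id, assay_id, cq`` plus optional
    ``run_id`` and ``condition``.  Wide format has a ``sample_id`` column,
    optional ``run_id``/``condition`` columns, and one column per assay.
    ``dialect`` may be ``"wide"``, ``"long"`` or ``"auto"`` (sniffed from
    the header).
    """
    tokens = tuple(undetermined_tokens)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'sample_id' column")
    is_long = dialect == "long" or (
        dialect == "auto" and {"assay_id", "cq"} <= set(df.columns)
    )
    if is_long:
        if not {"assay_id", "cq"} <= set(df.columns):
            raise FormatError(f"{path}: long format requires assay_id and cq columns")
        cq = [
            _parse_cq_cell(v, tokens, f"row {i + 2} (column 'cq')")
            for i, v in enumerate(df["cq"])
        ]
        work = df.assign(_cq=cq)
        values = work.pivot(index="sample_id", columns="assay_id", values="_cq")
        values = values.reindex(
            index=pd.unique(df["sample_id"]), columns=pd.unique(df["assay_id"])
        )
        values.index.name = None
        values.columns.name = None
        meta = df.drop_duplicates("sample_id").set_index("sample_id")
        run = meta["run_id"] if "run_id" in meta else pd.Series(
            default_run_id, index=values.index)
        cond = meta["condition"] if "condition" in meta else pd.Series(
            default_condition, index=values.index)
        return CqMatrix(values, run, cond)

    # wide
    df = df.set_index("sample_id")
    run = df.pop("run_id") if "run_id" in df.columns else pd.Series(
        default_run_id, index=df.index)
    cond = df.pop("condition") if "condition" in df.columns else pd.Series(
        default_condition, index=df.index)
    parsed = {}
    for col in df.columns:
        parsed[col] = [
            _parse_cq_cell(v, tokens, f"row {i + 2}, column {col!r}")
            for i, v in enumerate(df[col])
        ]
    values = pd.DataFrame(parsed, index=df.index)
    values.index.name = None
    return CqMatrix(values, run, cond)


def write_cq_table(cq: CqMatrix, path, undetermined_token: str = "Undetermined") -> None:
    """Write a Cq matrix in canonical long TSV format (lossless)."""
    rows = []
    for sample in cq.samples:
        run, cond = cq.run_id[sample], cq.condition[sample]
        for assay in cq.assays:
            v = cq.values.at[sample, assay]
            rows.append((
                sample, assay,
                undetermined_token if np.isnan(v) else repr(float(v)),
                run, cond,
            ))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tassay_id\tcq\trun_id\tcondition\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False, "": False}


def _parse_bool(raw: str, where: str) -> bool:
    try:
        return _BOOL[str(raw).strip().lower()]
    except KeyError:
        raise PanelValidationError(f"{where}: cannot parse boolean {raw!r}") from None


def read_assay_panel(path) -> AssayPanel:
    """Read an assay panel from TSV.

    ``intron_spanning`` defaults to true for assays whose id carries the
    ``_m`` suffix when the column is absent or empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"assay_id", "gene_symbol", "role"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: panel needs columns {sorted(required)}")
    assays = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        aid = row["assay_id"].strip()
        try:
            role = Role(row["role"].strip())
        except ValueError:
            raise PanelValidationError(f"{where}: unknown role {row['role']!r}") from None
        oc = row.get("or_class", "").strip()
        if oc:
            try:
                or_class = OrClass(oc)
            except ValueError:
                raise PanelValidationError(f"{where}: unknown or_class {oc!r}") from None
        else:
            or_class = OrClass.CLASS_II if role is Role.OR_TARGET else OrClass.NOT_APPLICABLE
        raw_intron = str(row.get("intron_spanning", "")).strip()
        intron = _parse_bool(raw_intron, where) if raw_intron else aid.endswith("_m")
        assays.append(Assay(
            assay_id=aid,
            gene_symbol=row["gene_symbol"].strip(),
            role=role,
            or_class=or_class,
            deorphanized=_parse_bool(row.get("deorphanized", "0"), where),
            agonist=str(row.get("agonist", "")).strip(),
            potentially_nonfunctional=_parse_bool(
                row.get("potentially_nonfunctional", "0"), where),
            intron_spanning=intron or aid.endswith("_m"),
        ))
    return AssayPanel(assays)


def write_assay_panel(panel: AssayPanel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("assay_id\tgene_symbol\trole\tor_class\tdeorphanized\t"
                 "agonist\tpotentially_nonfunctional\tintron_spanning\n")
        for a in panel.assays:
            fh.write("\t".join([
                a.assay_id, a.gene_symbol, a.role.value, a.or_class.value,
                "1" if a.deorphanized else "0", a.agonist,
                "1" if a.potentially_nonfunctional else "0",
                "1" if a.intron_spanning else "0",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("orqprofiler").joinpath("data", name)


def load_default_panel() -> AssayPanel:
    """The packaged 384-well panel: 356 OR targets, 10 endogenous
    references, 6 olfactory-epithelium references and GAPDH."""
    with importlib.resources.as_file(_data_path("default_panel.tsv")) as p:
        return read_assay_panel(p)


def load_table2_fixture() -> pd.DataFrame:
    """The 47 deorphanized receptors with printed mean ± sd copy numbers
    and expressing-individual counts.

    Returns a DataFrame with columns ``or_name, agonist, copies_mean,
    copies_sd, n_expressing``.
    """
    with importlib.resources.as_file(_data_path("deorphanized_receptors.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    if len(df) != 47:
        raise RuntimeError("deorphanized fixture corrupted: expected 47 rows")
    if not df["n_expressing"].between(0, 26).all():
        raise RuntimeError("deorphanized fixture corrupted: n_expressing out of range")
    return df


def read_sample_table(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(SampleRecord(
            sample_id=row["sample_id"],
            age=float(row["age"]),
            sex=row["sex"],
            rin=float(row["rin"]),
            smoking=Smoking(row["smoking"]),
            delay_hours=float(row["delay_hours"]),
            origin=row.get("origin", ""),
            cause_of_death=row.get("cause_of_death", ""),
        ))
    return records


def load_cohort_metadata() -> pd.DataFrame:
    """Packaged 26-donor cohort metadata table (13 F / 13 M, ages 39-81)."""
    with importlib.resources.as_file(_data_path("cohort_metadata.tsv")) as p:
        records = read_sample_table(p)
    return pd.DataFrame([r.__dict__ for r in records]).assign(
        smoking=lambda d: d["smoking"].map(lambda s: s.value)
    ).set_index("sample_id")
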