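"""Reading and writing of protein-groups LFQ tables, sample designs and curation flags.

The on-disk dialect is the MaxQuant ``proteinGroups.txt`` convention: a
tab-separated table with a ``Protein IDs`` column (semicolon-joined accession
groups), one ``LFQ intensity <sample>`` column per sample, and optional
``Reverse`` / ``Potential contaminant`` columns whose rows are flagged with
``+``. Zero intensities are treated as missing values (the MaxQuant
convention): a zero carries no quantitative information and the log transform
is undefined there.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SampleInfo",
    "SampleDesign",
    "LfqMatrix",
    "CurationFlags",
    "CurationTable",
    "DEFAULT_COLUMNS",
    "read_protein_groups",
    "write_protein_groups",
    "read_curation",
    "read_design",
    "write_design",
    "write_table",
]

PIPELINE_NAME = "decaplex"
PIPELINE_VERSION = "0.1.0"

#: valid sample groups: the tagged bait, the untagged parental control and the
#: free biotin-ligase (eYFP-TurboID) control used to flag bystander labelling
GROUPS = ("bait", "wt_control", "eyfp_control")


class ConfigurationError(ValueError):
    """Raised when an input file does not match the declared configuration."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    """Role of one sample column: which experiment, which group, which replicate."""

    experiment: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )


@dataclass
class SampleDesign:
    """Mapping of sample (column) names to their experimental role."""

    samples: dict[str, SampleInfo]

    @property
    def names(self) -> list[str]:
        return list(self.samples)

    def by_group(self, group: str, experiment: str | None = None) -> list[str]:
        """Sample names in ``group``, optionally restricted to one experiment."""
        return [
            name
            for name, info in self.samples.items()
            if info.group == group
            and (experiment is None or info.experiment == experiment)
        ]

    def experiments(self, group: str = "bait") -> list[str]:
        seen: dict[str, None] = {}
        for info in self.samples.values():
            if info.group == group:
                seen.setdefault(info.experiment, None)
        return list(seen)

    def validate(self, min_replicates: int = 2) -> None:
        groups: dict[tuple[str, str], int] = {}
        for info in self.samples.values():
            key = (info.experiment, info.group)
            groups[key] = groups.get(key, 0) + 1
        for (experiment, group), n in groups.items():
            if n < min_replicates:
                raise ConfigurationError(
                    f"group {group!r} of experiment {experiment!r} has {n} "
                    f"replicate(s); at least {min_replicates} are required"
                )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, object]]) -> "SampleDesign":
        samples = {
            str(name): SampleInfo(
                experiment=str(entry["experiment"]),
                group=str(entry["group"]),
                replicate=int(entry["replicate"]),
            )
            for name, entry in mapping.items()
        }
        return cls(samples)


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design from a tab-separated table.

    Expected columns: ``sample``, ``experiment``, ``group``, ``replicate``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "experiment", "group", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"design table lacks columns: {sorted(missing)}")
    samples: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        name = str(row["sample"])
        if name in samples:
            raise ConfigurationError(f"duplicate sample name {name!r} in design")
        samples[name] = SampleInfo(
            experiment=str(row["experiment"]),
            group=str(row["group"]),
            replicate=int(row["replicate"]),
        )
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str | Path) -> None:
    rows = [
        {
            "sample": name,
            "experiment": info.experiment,
            "group": info.group,
            "replicate": info.replicate,
        }
        for name, info in design.samples.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LFQ matrix
# ---------------------------------------------------------------------------

@dataclass
class LfqMatrix:
    """Protein x sample LFQ quantification matrix.

    ``values`` is a DataFrame indexed by protein-group id (the full
    semicolon-joined accession string) with one column per sample; missing
    quantifications are ``NaN``, which is distinct from a measured zero (and
    measured zeros are themselves treated as missing on read, per the
    MaxQuant convention).
    """

    values: pd.DataFrame
    log_transformed: bool = False
    gene_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.log_transformed:
            observed = self.values.to_numpy(dtype=float)
            if np.nanmin(observed, initial=0.0) < 0:
                raise ValueError("raw LFQ intensities must be non-negative")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein ids: {list(dupes)[:5]}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def observed_counts(self, samples: Iterable[str] | None = None) -> pd.Series:
        """Number of observed (non-missing) values per protein over ``samples``."""
        sub = self.values if samples is None else self.values[list(samples)]
        return sub.notna().sum(axis=1)

    def copy(self) -> "LfqMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_names=None if self.gene_names is None else self.gene_names.copy(),
        )


# ---------------------------------------------------------------------------
# curation flags
# ---------------------------------------------------------------------------

_FLAG_NAMES = (
    "mrna_metabolism",
    "pp_localization",
    "sg_localization",
    "allowlist",
    "denylist",
)

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", "", "nan"}


@dataclass(frozen=True)
class CurationFlags:
    """Literature-derived per-protein annotations used by the filter cascade.

    These are user-supplied judgements (mRNA-metabolism link, posterior-pole
    or stress-granule localization, allow/deny overrides) and are never
    inferred by the pipeline.
    """

    mrna_metabolism: bool = False
    pp_localization: bool = False
    sg_localization: bool = False
    allowlist: bool = False
    denylist: bool = False


@dataclass
class CurationTable:
    """Lookup of curation flags; unknown proteins default to all-false."""

    flags: dict[str, CurationFlags] = field(default_factory=dict)

    def get(self, protein_id: str) -> CurationFlags:
        if protein_id in self.flags:
            return self.flags[protein_id]
        # protein groups carry semicolon-joined accessions; curation entries
        # are keyed by the leading accession
        leading = protein_id.split(";")[0]
        return self.flags.get(leading, CurationFlags())

    def __len__(self) -> int:
        return len(self.flags)


def _parse_bool(raw: object, row: int, column: str) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ConfigurationError(
        f"cannot parse boolean {raw!r} in column {column!r}, row {row}"
    )


def read_curation(path: str | Path) -> CurationTable:
    """Read a curation annotation table (TSV or CSV, auto-detected).

    The table needs a ``protein_id`` column; any of the flag columns
    {mrna_metabolism, pp_localization, sg_localization, allowlist, denylist}
    may be present, with case-insensitive truthy values (true/1/yes).
    An empty file yields an empty table whose lookups default to all-false.
    """
    text = Path(path).read_text()
    if not text.strip():
        return CurationTable()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "protein_id" not in df.columns:
        raise ConfigurationError("curation table lacks a 'protein_id' column")
    flags: dict[str, CurationFlags] = {}
    for i, row in df.iterrows():
        values = {
            name: _parse_bool(row[name], int(i) + 2, name)
            for name in _FLAG_NAMES
            if name in df.columns and pd.notna(row[name])
        }
        flags[str(row["protein_id"]).strip()] = CurationFlags(**values)
    return CurationTable(flags)


# ---------------------------------------------------------------------------
# protein-groups reader / writer
# ---------------------------------------------------------------------------

#: default MaxQuant proteinGroups.txt column names; overridable because the
#: exact header layout varies between MaxQuant versions
DEFAULT_COLUMNS = {
    "protein_ids": "Protein IDs",
    "gene_names": "Gene names",
    "lfq_prefix": "LFQ intensity ",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    columns: Mapping[str, str] | None = None,
) -> LfqMatrix:
    """Read a protein-groups table into an :class:`LfqMatrix`.

    Rows flagged as decoy (``Reverse``) or ``Potential contaminant`` are
    dropped; zero intensities become missing values; columns are returned in
    design order.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(columns)

    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if cols["protein_ids"] not in df.columns:
        raise ConfigurationError(
            f"protein-groups table lacks identifier column {cols['protein_ids']!r}"
        )

    # contaminant / decoy filtering; absent flag columns mean no filtering
    for key in ("reverse", "contaminant"):
        col = cols[key]
        if col in df.columns:
            df = df[df[col].fillna("") != "+"]

    ids = df[cols["protein_ids"]].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ConfigurationError(f"duplicate protein ids: {dupes[:5]}")

    sample_cols = {}
    for name in design.names:
        col = cols["lfq_prefix"] + name
        if col not in df.columns:
            raise ConfigurationError(
                f"sample {name!r} declared in design but column {col!r} is "
                "absent from the protein-groups table"
            )
        sample_cols[name] = col

    values = (
        df[list(sample_cols.values())]
        .apply(pd.to_numeric, errors="coerce")
        .set_axis(list(sample_cols), axis=1)
    )
    values.index = pd.Index(ids, name="protein_id")
    values = values.replace(0.0, np.nan)

    gene_names = None
    if cols["gene_names"] in df.columns:
        gene_names = df[cols["gene_names"]].set_axis(values.index)

    return LfqMatrix(values=values, log_transformed=False, gene_names=gene_names)


def _header_comment(params: Mapping[str, object] | None) -> str:
    parts = [f"# {PIPELINE_NAME} v{PIPELINE_VERSION}"]
    if params:
        parts += [f"# {key} = {value}" for key, value in params.items()]
    return "\n".join(parts) + "\n"


def write_protein_groups(
    matrix: LfqMatrix,
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write an :class:`LfqMatrix` in the protein-groups TSV dialect.

    Missing values are written as 0 (raw matrices) so that a round trip
    through :func:`read_protein_groups` restores the same missingness mask.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    out = pd.DataFrame({cols["protein_ids"]: matrix.protein_ids})
    if matrix.gene_names is not None:
        out[cols["gene_names"]] = matrix.gene_names.to_numpy()
    for name in matrix.sample_names:
        col = matrix.values[name]
        out[cols["lfq_prefix"] + name] = col.fillna(0.0).to_numpy()
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    """Write a result table as TSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index=index)
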