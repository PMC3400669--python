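"""Reading, validation and reconstruction of per-study genotype count data.

A *study* is one case-control comparison with genotype counts (GG/GA/AA)
in each arm plus two stratum labels (ethnicity, source of controls).
Published tables often print genotype *proportions* rather than raw
counts; :func:`reconstruct_counts` recovers integer counts from a sample
size and a rounded proportion triple.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GenotypeCounts",
    "Ethnicity",
    "ControlSource",
    "Study",
    "StudyCollection",
    "reconstruct_counts",
    "parse_study_table",
    "write_study_table",
    "bundled_fixture",
    "COUNT_COLUMNS",
    "FREQ_COLUMNS",
]

#: sum-to-one tolerance for printed proportion triples (3-decimal rounding)
PROPORTION_SUM_TOL = 0.02

META_COLUMNS = ["study", "year", "ethnicity", "source", "n_case", "n_control"]
COUNT_COLUMNS = {
    "case": ["case_GG", "case_GA", "case_AA"],
    "control": ["ctrl_GG", "ctrl_GA", "ctrl_AA"],
}
FREQ_COLUMNS = {
    "case": ["case_fGG", "case_fGA", "case_fAA"],
    "control": ["ctrl_fGG", "ctrl_fGA", "ctrl_fAA"],
}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm of one study."""

    n_GG: int
    n_GA: int
    n_AA: int

    def __post_init__(self) -> None:
        for name in ("n_GG", "n_GA", "n_AA"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value}")
        if self.total < 1:
            raise ValidationError("genotype counts must sum to at least 1")

    @property
    def total(self) -> int:
        return self.n_GG + self.n_GA + self.n_AA

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_GG, self.n_GA, self.n_AA)

    def proportions(self) -> tuple[float, float, float]:
        n = self.total
        return (self.n_GG / n, self.n_GA / n, self.n_AA / n)


class Ethnicity(Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"

    @classmethod
    def parse(cls, text: str) -> "Ethnicity":
        key = str(text).strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        raise ValidationError(
            f"unknown ethnicity {text!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class ControlSource(Enum):
    HOSPITAL = "Hospital"
    POPULATION = "Population"

    @classmethod
    def parse(cls, text: str) -> "ControlSource":
        key = str(text).strip().lower()
        # accept the common "-based" suffix
        key = key.removesuffix("-based").removesuffix(" based")
        for member in cls:
            if member.value.lower() == key:
                return member
        raise ValidationError(
            f"unknown control source {text!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class Study:
    """A labelled case-control comparison with stratum metadata."""

    label: str
    ethnicity: Ethnicity
    control_source: ControlSource
    cases: GenotypeCounts
    controls: GenotypeCounts
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.label or not str(self.label).strip():
            raise ValidationError("study label must be non-empty")
        if not isinstance(self.ethnicity, Ethnicity):
            raise ValidationError(f"ethnicity must be an Ethnicity, got {self.ethnicity!r}")
        if not isinstance(self.control_source, ControlSource):
            raise ValidationError(
                f"control_source must be a ControlSource, got {self.control_source!r}"
            )

    @property
    def n_case(self) -> int:
        return self.cases.total

    @property
    def n_control(self) -> int:
        return self.controls.total


@dataclass(frozen=True)
class StudyCollection:
    """Ordered collection of studies with unique labels."""

    studies: tuple[Study, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        labels = [s.label for s in self.studies]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate study labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[Study]:
        return iter(self.studies)

    def __getitem__(self, key: int | str) -> Study:
        if isinstance(key, str):
            for s in self.studies:
                if s.label == key:
                    return s
            raise KeyError(key)
        return self.studies[key]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.studies)

    @property
    def total_cases(self) -> int:
        return sum(s.n_case for s in self.studies)

    @property
    def total_controls(self) -> int:
        return sum(s.n_control for s in self.studies)

    def drop(self, label: str) -> "StudyCollection":
        """Collection with one study removed (for leave-one-out)."""
        if label not in self.labels:
            raise KeyError(label)
        return replace(
            self,
            studies=tuple(s for s in self.studies if s.label != label),
        )

    def subset(self, labels: Iterable[str]) -> "StudyCollection":
        wanted = list(labels)
        missing = [l for l in wanted if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in collection: {missing}")
        return replace(
            self, studies=tuple(s for s in self.studies if s.label in wanted)
        )

    def partition(self, stratifier: str) -> list[tuple[str, "StudyCollection"]]:
        """Partition by ``"ethnicity"`` or ``"control_source"``.

        Strata appear in order of first appearance in the collection.
        """
        if stratifier not in ("ethnicity", "control_source"):
            raise ValidationError(
                f"stratifier must be 'ethnicity' or 'control_source', got {stratifier!r}"
            )
        order: list[str] = []
        groups: dict[str, list[Study]] = {}
        for s in self.studies:
            key = getattr(s, stratifier).value
            if key not in groups:
                order.append(key)
                groups[key] = []
            groups[key].append(s)
        return [
            (key, replace(self, studies=tuple(groups[key]))) for key in order
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            rows.append(
                {
                    "study": s.label,
                    "year": s.year,
                    "ethnicity": s.ethnicity.value,
                    "source": s.control_source.value,
                    "n_case": s.n_case,
                    "n_control": s.n_control,
                    "case_GG": s.cases.n_GG,
                    "case_GA": s.cases.n_GA,
                    "case_AA": s.cases.n_AA,
                    "ctrl_GG": s.controls.n_GG,
                    "ctrl_GA": s.controls.n_GA,
                    "ctrl_AA": s.controls.n_AA,
                }
            )
        return pd.DataFrame(rows)


def reconstruct_counts(
    n: int,
    freqs: Sequence[float],
    *,
    tol: float = PROPORTION_SUM_TOL,
    label: str = "",
) -> GenotypeCounts:
    """Recover integer genotype counts from a sample size and proportions.

    Each cell is rounded to the nearest integer; if the rounded triple
    does not sum to ``n`` the discrepancy is repaired one unit at a time
    on the cell with the largest remainder in the needed direction
    (largest-remainder correction).  The result always sums exactly to
    ``n`` and minimises the maximum absolute deviation from ``n*freq``.

    Parameters
    ----------
    n : arm sample size (>= 1)
    freqs : three genotype proportions (GG, GA, AA), each in [0, 1],
        summing to 1 within ``tol`` (printed tables are rounded).
    """
    where = f" in row {label!r}" if label else ""
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}{where}")
    freqs = tuple(float(f) for f in freqs)
    if len(freqs) != 3:
        raise ValidationError(f"expected 3 proportions, got {len(freqs)}{where}")
    if any(f < 0 or f > 1 for f in freqs):
        raise ValidationError(f"proportions must lie in [0, 1]: {freqs}{where}")
    total = sum(freqs)
    if abs(total - 1.0) > tol:
        raise ValidationError(
            f"proportions sum to {total:.4f}, outside 1 +/- {tol}{where}"
        )

    targets = [n * f for f in freqs]
    counts = [round(t) for t in targets]
    remainders = [t - c for t, c in zip(targets, counts)]
    diff = n - sum(counts)
    while diff != 0:
        step = 1 if diff > 0 else -1
        idx = max(range(3), key=lambda i: (step * remainders[i], -counts[i] * step))
        counts[idx] += step
        remainders[idx] -= step
        diff -= step
    if any(c < 0 for c in counts):  # pragma: no cover - unreachable for valid input
        raise ValidationError(f"reconstruction produced negative counts{where}")
    return GenotypeCounts(*counts)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _arm_counts(row: pd.Series, arm: str, label: str) -> GenotypeCounts:
    """Extract one arm's counts from a parsed row (count or frequency mode)."""
    count_cols = COUNT_COLUMNS[arm]
    freq_cols = FREQ_COLUMNS[arm]
    have_counts = [c for c in count_cols if c in row.index and pd.notna(row[c])]
    have_freqs = [c for c in freq_cols if c in row.index and pd.notna(row[c])]
    n_declared = int(row["n_case" if arm == "case" else "n_control"])

    if have_counts and have_freqs:
        raise ValidationError(
            f"row {label!r}: mixed counts and proportions in the {arm} arm"
        )
    if len(have_counts) == 3:
        counts = GenotypeCounts(*(int(row[c]) for c in count_cols))
        if counts.total != n_declared:
            raise ValidationError(
                f"row {label!r}: {arm} counts sum to {counts.total}, "
                f"declared sample size is {n_declared}"
            )
        return counts
    if len(have_freqs) == 3:
        return reconstruct_counts(
            n_declared, [float(row[c]) for c in freq_cols], label=label
        )
    raise ValidationError(
        f"row {label!r}: the {arm} arm needs all three count columns "
        f"({count_cols}) or all three frequency columns ({freq_cols})"
    )


def parse_study_table(
    path_or_buffer,
    *,
    delimiter: str | None = None,
    provenance: str = "",
) -> StudyCollection:
    """Parse a delimited study table into a validated :class:`StudyCollection`.

    The delimiter is auto-detected from the header line (tab if present,
    else comma) unless given explicitly.  Each arm of each row may carry
    either explicit genotype counts or proportions; proportion rows are
    reconstructed via :func:`reconstruct_counts`.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
        provenance = provenance or str(path_or_buffer)
    if not text.strip():
        raise ParseError("empty study table")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])

    df = pd.read_csv(io.StringIO(text), sep=delimiter)
    missing = [c for c in META_COLUMNS if c not in df.columns and c != "year"]
    if missing:
        raise ParseError(f"missing required column(s): {missing}")

    studies = []
    for _, row in df.iterrows():
        label = str(row["study"]).strip()
        year = None
        if "year" in df.columns and pd.notna(row.get("year")):
            year = int(row["year"])
        studies.append(
            Study(
                label=label,
                year=year,
                ethnicity=Ethnicity.parse(row["ethnicity"]),
                control_source=ControlSource.parse(row["source"]),
                cases=_arm_counts(row, "case", label),
                controls=_arm_counts(row, "control", label),
            )
        )
    return StudyCollection(studies=tuple(studies), provenance=provenance)


def write_study_table(
    collection: StudyCollection, path_or_buffer, *, delimiter: str = ","
) -> None:
    """Write a collection in count mode, round-trippable by ``parse_study_table``."""
    df = collection.to_dataframe()
    if hasattr(path_or_buffer, "write"):
        df.to_csv(path_or_buffer, sep=delimiter, index=False)
    else:
        with open(path_or_buffer, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, sep=delimiter, index=False)


def bundled_fixture() -> StudyCollection:
    """The bundled seven-study case-control collection (count mode).

    Counts were reconstructed from the published per-study sample sizes
    and genotype proportions with :func:`reconstruct_counts`.
    """
    ref = resources.files("snpmeta.data").joinpath("seven_study_glioma.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return parse_study_table(
            fh, provenance="bundled seven-study glioma case-control fixture"
        )
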