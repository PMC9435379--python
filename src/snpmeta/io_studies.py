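"""Reading, validation and participant accounting for study-level SNP data.

The input schema is one row per (study x SNP): ancestry labels, case/control
totals, genotype counts ``AA/AG/GG`` for cases and controls, and optionally a
reported odds ratio with its 95% CI for studies that publish only a summary
effect.  ``NR`` (not reported) and the empty string are the only recognised
missing-value tokens.

Columns (UTF-8, tab- or comma-separated, ``.`` decimal separator)::

    study_id    snp_id      population  subgroup    cohort_id
    n_case      n_control
    case_AA     case_AG     case_GG
    control_AA  control_AG  control_GG
    or_point    or_ci_low   or_ci_high

``cohort_id`` identifies the underlying participant cohort and drives
de-duplication in :func:`account_participants`: a cohort genotyped for two
SNPs contributes two analysis rows but its participants are counted once.

The packaged fixture (``data/table1.tsv``) transcribes the characteristics
table of a published ischemic-stroke meta-analysis of the *PITX2* variants
rs2200733 and rs6843082: nine case-control studies from eight articles, with
study labels following the first author where the source names one and the
source's bibliography tag otherwise.  Both rows of the Su cohort share one
``cohort_id`` because that cohort was genotyped for both SNPs.  The Bevan row
carries neither genotype counts nor a reported effect (all cells ``NR``) and
is therefore carried through validation as data-unavailable and excluded,
with a logged reason, from every analysis.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

#: Tokens interpreted as a missing count or effect cell.
MISSING_TOKENS = frozenset({"", "NR"})

#: Required input columns, in canonical order.
SCHEMA: tuple[str, ...] = (
    "study_id", "snp_id", "population", "subgroup", "cohort_id",
    "n_case", "n_control",
    "case_AA", "case_AG", "case_GG",
    "control_AA", "control_AG", "control_GG",
    "or_point", "or_ci_low", "or_ci_high",
)


class SchemaError(ValueError):
    """The input header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


@dataclass(frozen=True)
class StudyRecord:
    """One (study x SNP) row of a meta-analysis input table.

    Exactly one of ``case_counts``/``control_counts`` (as a pair) or
    ``effect_only`` should be present for a row to be analysable; a record
    with neither is valid but data-unavailable and is excluded from every
    analysis with a logged reason.  Carrying both is an error.
    """

    study_id: str
    snp_id: str
    population: str
    subgroup: str
    cohort_id: str
    n_case: int
    n_control: int
    case_counts: tuple[int, int, int] | None = None
    control_counts: tuple[int, int, int] | None = None
    effect_only: tuple[float, float, float] | None = None  # (OR, lo, hi)

    def __post_init__(self) -> None:
        if not self.study_id or not self.snp_id:
            raise ValidationError("study_id and snp_id are required")
        if not self.subgroup:
            raise ValidationError(
                f"{self.study_id}/{self.snp_id}: subgroup missing and not "
                "derivable; supply a population->subgroup mapping"
            )
        if self.n_case < 0 or self.n_control < 0:
            raise ValidationError(
                f"{self.study_id}/{self.snp_id}: negative participant count"
            )
        if (self.case_counts is None) != (self.control_counts is None):
            raise ValidationError(
                f"{self.study_id}/{self.snp_id}: genotype counts must be "
                "present for both cases and controls or neither"
            )
        if self.has_counts and self.effect_only is not None:
            raise ValidationError(
                f"{self.study_id}/{self.snp_id}: both genotype counts and a "
                "reported effect present; supply exactly one"
            )
        if self.has_counts:
            for label, counts, n in (
                ("case", self.case_counts, self.n_case),
                ("control", self.control_counts, self.n_control),
            ):
                if any(c < 0 for c in counts):
                    raise ValidationError(
                        f"{self.study_id}/{self.snp_id}: negative {label} "
                        "genotype count"
                    )
                if sum(counts) != n:
                    raise ValidationError(
                        f"{self.study_id}/{self.snp_id}: {label} genotype "
                        f"counts sum to {sum(counts)}, expected {n}"
                    )
        if self.effect_only is not None:
            or_point, lo, hi = self.effect_only
            if not (0 < lo <= or_point <= hi):
                raise ValidationError(
                    f"{self.study_id}/{self.snp_id}: reported effect must "
                    f"satisfy 0 < ci_low <= OR <= ci_high, got {self.effect_only}"
                )

    @property
    def has_counts(self) -> bool:
        return self.case_counts is not None

    @property
    def has_effect(self) -> bool:
        return self.effect_only is not None

    @property
    def unavailable(self) -> bool:
        """True when the row carries neither counts nor a reported effect."""
        return not (self.has_counts or self.has_effect)


@dataclass(frozen=True)
class ParticipantAccounting:
    """Participant totals with cohort-level de-duplication.

    ``total_*`` count each ``cohort_id`` once even when it contributes rows
    for several SNPs; ``per_snp_*`` sum rows per SNP without de-duplication.
    """

    total_participants: int
    total_cases: int
    total_controls: int
    per_snp_cases: dict[str, int] = field(default_factory=dict)
    per_snp_controls: dict[str, int] = field(default_factory=dict)


def _parse_cell(value: str | None, row_label: str, column: str) -> int | None:
    value = (value or "").strip()
    if value in MISSING_TOKENS:
        return None
    try:
        parsed = int(value)
    except ValueError:
        raise ValidationError(
            f"{row_label}: column {column!r} is not an integer: {value!r}"
        ) from None
    if parsed < 0:
        raise ValidationError(f"{row_label}: negative count in {column!r}")
    return parsed


def _parse_float(value: str | None, row_label: str, column: str) -> float | None:
    value = (value or "").strip()
    if value in MISSING_TOKENS:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"{row_label}: column {column!r} is not numeric: {value!r}"
        ) from None


def _triple(values: Sequence[int | None], row_label: str, label: str
            ) -> tuple[int, int, int] | None:
    present = [v is not None for v in values]
    if not any(present):
        return None
    if not all(present):
        raise ValidationError(
            f"{row_label}: partial {label} genotype triple; supply all of "
            "AA, AG, GG or none"
        )
    return tuple(values)  # type: ignore[return-value]


def read_study_table(
    path: str | Path,
    subgroup_map: Mapping[str, str] | None = None,
    *,
    tolerate_sums: bool = False,
) -> list[StudyRecord]:
    """Read and validate a study table from a TSV/CSV file.

    Parameters
    ----------
    path
        Input file.  The delimiter is taken as a tab when the header line
        contains one, otherwise a comma.
    subgroup_map
        Explicit population -> subgroup mapping used only for rows whose
        ``subgroup`` cell is empty.  A row that needs it but has no mapping
        entry is rejected: subgroups are never guessed silently.
    tolerate_sums
        When true, rows whose genotype counts disagree with the printed
        ``n_case``/``n_control`` are accepted with a warning and ``n``
        recomputed from the counts instead of being rejected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        header_line = handle.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file, expected header {SCHEMA}")
        delimiter = "\t" if "\t" in header_line else ","
        header = [h.strip() for h in header_line.rstrip("\r\n").split(delimiter)]
        missing = [c for c in SCHEMA if c not in header]
        if missing:
            raise SchemaError(f"{path}: header missing column(s) {missing}")
        reader = csv.DictReader(handle, fieldnames=header, delimiter=delimiter)
        records = []
        for lineno, row in enumerate(reader, start=2):
            row_label = f"{path.name}:{lineno}"
            n_case = _parse_cell(row.get("n_case"), row_label, "n_case")
            n_control = _parse_cell(row.get("n_control"), row_label, "n_control")
            if n_case is None or n_control is None:
                raise ValidationError(f"{row_label}: n_case/n_control required")
            case_counts = _triple(
                [_parse_cell(row.get(c), row_label, c)
                 for c in ("case_AA", "case_AG", "case_GG")],
                row_label, "case")
            control_counts = _triple(
                [_parse_cell(row.get(c), row_label, c)
                 for c in ("control_AA", "control_AG", "control_GG")],
                row_label, "control")
            effect_cells = [
                _parse_float(row.get(c), row_label, c)
                for c in ("or_point", "or_ci_low", "or_ci_high")]
            if any(v is not None for v in effect_cells):
                if any(v is None for v in effect_cells):
                    raise ValidationError(
                        f"{row_label}: partial reported effect; supply all of "
                        "or_point, or_ci_low, or_ci_high or none")
                effect_only = (effect_cells[0], effect_cells[1], effect_cells[2])
            else:
                effect_only = None

            if tolerate_sums and case_counts is not None:
                if sum(case_counts) != n_case:
                    logger.warning(
                        "%s: case counts sum to %d, not %d; recomputing n_case",
                        row_label, sum(case_counts), n_case)
                    n_case = sum(case_counts)
                if sum(control_counts) != n_control:
                    logger.warning(
                        "%s: control counts sum to %d, not %d; "
                        "recomputing n_control",
                        row_label, sum(control_counts), n_control)
                    n_control = sum(control_counts)

            population = (row.get("population") or "").strip()
            subgroup = (row.get("subgroup") or "").strip()
            if not subgroup:
                if subgroup_map is None or population not in subgroup_map:
                    raise ValidationError(
                        f"{row_label}: subgroup blank and population "
                        f"{population!r} absent from the subgroup mapping")
                subgroup = subgroup_map[population]
            study_id = (row.get("study_id") or "").strip()

            try:
                record = StudyRecord(
                    study_id=study_id,
                    snp_id=(row.get("snp_id") or "").strip(),
                    population=population,
                    subgroup=subgroup,
                    cohort_id=(row.get("cohort_id") or "").strip() or study_id,
                    n_case=n_case,
                    n_control=n_control,
                    case_counts=case_counts,
                    control_counts=control_counts,
                    effect_only=effect_only,
                )
            except ValidationError as err:
                raise ValidationError(f"{row_label}: {err}") from None
            records.append(record)
    return records


def write_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records in the canonical TSV schema (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(SCHEMA)
        for r in records:
            case = r.case_counts or ("NR",) * 3
            ctrl = r.control_counts or ("NR",) * 3
            eff = r.effect_only or ("", "", "")
            writer.writerow([
                r.study_id, r.snp_id, r.population, r.subgroup, r.cohort_id,
                r.n_case, r.n_control, *case, *ctrl,
                *(repr(v) if v != "" else "" for v in eff),
            ])


def flip_alleles(record: StudyRecord) -> StudyRecord:
    """Swap the coded allele of one row: reverse (AA, AG, GG) to (GG, AG, AA)
    and invert a reported OR/CI.  Off by default everywhere; counts are
    otherwise analysed exactly as printed, with no cross-study risk-allele
    harmonisation."""
    effect = record.effect_only
    if effect is not None:
        or_point, lo, hi = effect
        effect = (1.0 / or_point, 1.0 / hi, 1.0 / lo)
    return replace(
        record,
        case_counts=record.case_counts[::-1] if record.case_counts else None,
        control_counts=record.control_counts[::-1] if record.control_counts else None,
        effect_only=effect,
    )


def account_participants(records: Sequence[StudyRecord]) -> ParticipantAccounting:
    """Aggregate participant totals over a validated record list.

    Grand totals count each ``cohort_id`` once (first row encountered);
    per-SNP totals sum rows for that SNP without de-duplication.
    """
    seen: dict[str, tuple[int, int]] = {}
    per_snp_cases: dict[str, int] = {}
    per_snp_controls: dict[str, int] = {}
    for r in records:
        seen.setdefault(r.cohort_id, (r.n_case, r.n_control))
        per_snp_cases[r.snp_id] = per_snp_cases.get(r.snp_id, 0) + r.n_case
        per_snp_controls[r.snp_id] = per_snp_controls.get(r.snp_id, 0) + r.n_control
    total_cases = sum(c for c, _ in seen.values())
    total_controls = sum(c for _, c in seen.values())
    return ParticipantAccounting(
        total_participants=total_cases + total_controls,
        total_cases=total_cases,
        total_controls=total_controls,
        per_snp_cases=per_snp_cases,
        per_snp_controls=per_snp_controls,
    )


def fixture_path() -> Path:
    """Path to the packaged nine-study ischemic-stroke fixture table."""
    return Path(resources.files("snpmeta").joinpath("data/table1.tsv"))


def load_fixture() -> list[StudyRecord]:
    """Load the packaged nine-study rs2200733/rs6843082 fixture."""
    return read_study_table(fixture_path())
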