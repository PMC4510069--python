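"""Multi-assay sample-sheet model: parsing, validation and queries.

The sheet layout mirrors the public inventory of the GEO series GSE51011
(94 high-throughput sequencing samples: ChIP-seq for Myc, RNAPII and
histone marks, total RNA-seq, 4sU-seq and DNAseI-seq across mouse and
human Myc model systems), which ships with the package as a TSV fixture.
One row is one sequencing sample; columns:

``sample_id`` (GSM accession), ``name``, ``rep`` ("index/total"),
``data_type`` (ChIP-Seq | RNA-Seq | DNAse-Seq), ``target`` (antibody or
RNA fraction; "–" for none, e.g. inputs), ``org`` (mmu | hsa, mapping to
genome builds mm9 / hg18), ``model`` (biological system), and
``input_baseline`` — the sample(s) serving as ChIP input or expression
baseline, either a single accession, a dash-truncated range such as
``GSM1234734-7`` (= GSM1234734..GSM1234737), or "–" for none.

Unicode in model names (Eμ-myc) is kept verbatim but matched through an
ASCII alias (Eu-myc), so queries work regardless of how the name was
transcribed.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

#: markers used for "no value" in the sheet (en-dash in most rows, a
#: plain hyphen in a few) — all normalised to None/empty on parse
NA_MARKERS = {"–", "-", "—", ""}

ORG_TO_GENOME = {"mmu": "mm9", "hsa": "hg18"}

VALID_DATA_TYPES = {"ChIP-Seq", "RNA-Seq", "DNAse-Seq"}

_MODEL_ALIASES = {"eμ-myc": "Eu-myc", "eu-myc": "Eu-myc"}

_SHEET_COLUMNS = [
    "sample_id", "name", "rep", "data_type", "target", "org", "model",
    "input_baseline",
]


def normalize_model(model: str) -> str:
    """Canonical ASCII alias for a biological-model name (Eμ-myc → Eu-myc)."""
    return _MODEL_ALIASES.get(model.strip().lower(), model.strip())


class Severity(Enum):
    WARNING = "WARNING"
    ERROR = "ERROR"


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    severity: Severity
    sample_id: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.value}\t{self.sample_id}\t{self.message}"


@dataclass(frozen=True, slots=True)
class SampleRecord:
    """One sequencing sample with replicate bookkeeping and baseline links."""

    sample_id: str
    name: str
    replicate_index: int
    replicate_total: int
    data_type: str
    target: str | None
    organism: str
    model: str
    baseline_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 1 <= self.replicate_index <= self.replicate_total:
            raise ValueError(
                f"{self.sample_id}: replicate_index {self.replicate_index} "
                f"outside 1..{self.replicate_total}"
            )
        if self.data_type not in VALID_DATA_TYPES:
            raise ValueError(f"{self.sample_id}: unknown data_type {self.data_type!r}")
        if self.organism not in ORG_TO_GENOME:
            raise ValueError(f"{self.sample_id}: unknown organism {self.organism!r}")

    @property
    def genome(self) -> str:
        """Reference genome build implied by the organism (mmu→mm9, hsa→hg18)."""
        return ORG_TO_GENOME[self.organism]

    @property
    def model_alias(self) -> str:
        return normalize_model(self.model)

    @property
    def is_input(self) -> bool:
        """Heuristic: a sample used as background/baseline, never analysed alone."""
        return ".input" in self.name or self.name.endswith("input")


_RANGE_RE = re.compile(r"^(GSM\d+)-(\d+)$")
_SINGLE_RE = re.compile(r"^GSM\d+$")


def expand_baseline_reference(ref: str) -> list[str]:
    """Expand a baseline cell into explicit accessions.

    Handles three forms: a plain accession; a dash-truncated range whose
    right endpoint replaces the trailing digits of the left accession
    (``GSM1234734-7`` → GSM1234734, GSM1234735, GSM1234736, GSM1234737);
    and a no-value marker, which yields an empty list.
    """
    ref = ref.strip()
    if ref in NA_MARKERS:
        return []
    if _SINGLE_RE.match(ref):
        return [ref]
    m = _RANGE_RE.match(ref)
    if not m:
        raise ValueError(f"unparseable baseline reference {ref!r}")
    left, right = m.group(1), m.group(2)
    left_digits = left[3:]
    hi = int(left_digits[: len(left_digits) - len(right)] + right)
    lo = int(left_digits)
    if hi <= lo:
        raise ValueError(
            f"baseline range {ref!r}: right endpoint {hi} must exceed left {lo}"
        )
    return [f"GSM{i}" for i in range(lo, hi + 1)]


def _parse_rep(rep: str, sample_id: str) -> tuple[int, int]:
    m = re.match(r"^(\d+)\s*/\s*(\d+)$", rep.strip())
    if not m:
        raise ValueError(f"{sample_id}: malformed replicate field {rep!r}")
    return int(m.group(1)), int(m.group(2))


def parse_sample_sheet(path) -> list[SampleRecord]:
    """Read a TSV sample sheet into records; raises on malformed rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        idx, total = _parse_rep(row.rep, row.sample_id)
        target = None if row.target.strip() in NA_MARKERS else row.target.strip()
        records.append(
            SampleRecord(
                sample_id=row.sample_id.strip(),
                name=row.name.strip(),
                replicate_index=idx,
                replicate_total=total,
                data_type=row.data_type.strip(),
                target=target,
                organism=row.org.strip(),
                model=row.model.strip(),
                baseline_ids=tuple(expand_baseline_reference(row.input_baseline)),
            )
        )
    return records


def load_packaged_sheet() -> list[SampleRecord]:
    """The sample sheet shipped with the package (GSE51011 inventory, 94 rows)."""
    resource = importlib.resources.files("stallkit") / "data" / "gse51011_samples.tsv"
    with importlib.resources.as_file(resource) as path:
        return parse_sample_sheet(path)


def write_sample_sheet(records: list[SampleRecord], path) -> None:
    """Write records back to TSV (inverse of :func:`parse_sample_sheet`)."""
    rows = []
    for r in records:
        if len(r.baseline_ids) == 0:
            baseline = "–"
        elif len(r.baseline_ids) == 1:
            baseline = r.baseline_ids[0]
        else:
            baseline = _compress_range(r.baseline_ids)
        rows.append(
            {
                "sample_id": r.sample_id,
                "name": r.name,
                "rep": f"{r.replicate_index}/{r.replicate_total}",
                "data_type": r.data_type,
                "target": r.target if r.target is not None else "–",
                "org": r.organism,
                "model": r.model,
                "input_baseline": baseline,
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def _compress_range(ids: tuple[str, ...]) -> str:
    nums = [int(i[3:]) for i in ids]
    if nums == list(range(nums[0], nums[0] + len(nums))):
        last = str(nums[-1])
        first = str(nums[0])
        # truncate the right endpoint to the digits that differ
        for k in range(1, len(last)):
            if int(first[:-k] + last[-k:]) == nums[-1]:
                continue
            return f"GSM{first}-{last[-(k - 1):]}" if k > 1 else f"GSM{first}-{last}"
        return f"GSM{first}-{last[-1]}"
    return ",".join(ids)


_REP_SUFFIX_RE = re.compile(r"(\.B|[._]?\d+)$")


def _replicate_set_key(r: SampleRecord) -> tuple:
    stem = _REP_SUFFIX_RE.sub("", r.name)
    return (r.model_alias, r.data_type, r.target, stem)


def validate_sheet(records: list[SampleRecord]) -> list[ValidationIssue]:
    """Cross-check internal linkage; an empty result means a clean sheet.

    ERROR issues: duplicate sample ids; baseline references that do not
    resolve to a row in the sheet.  WARNING issues: replicate sets whose
    observed row count differs from the declared total; input rows that
    nonetheless declare a target (present verbatim in the published
    inventory, surfaced rather than silently accepted).
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            issues.append(
                ValidationIssue(Severity.ERROR, r.sample_id, "duplicate sample_id")
            )
        seen.add(r.sample_id)

    ids = {r.sample_id for r in records}
    for r in records:
        for b in r.baseline_ids:
            if b not in ids:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR, r.sample_id,
                        f"baseline {b} not present in the sheet",
                    )
                )
        if r.is_input and r.target is not None:
            issues.append(
                ValidationIssue(
                    Severity.WARNING, r.sample_id,
                    f"input row declares target {r.target!r}",
                )
            )

    # replicate sets: rows declaring a shared total > 1 should exist in
    # exactly that number, with distinct indices
    groups: dict[tuple, list[SampleRecord]] = {}
    for r in records:
        if r.replicate_total > 1:
            groups.setdefault(_replicate_set_key(r), []).append(r)
    for key, members in groups.items():
        totals = {m.replicate_total for m in members}
        declared = max(totals)
        indices = sorted(m.replicate_index for m in members)
        if len(members) != declared or indices != list(range(1, declared + 1)):
            issues.append(
                ValidationIssue(
                    Severity.WARNING, members[0].sample_id,
                    f"replicate set {key[3]!r}: observed {len(members)} rows "
                    f"(indices {indices}) vs declared total {declared}",
                )
            )
    return issues


def query(
    records: list[SampleRecord],
    model: str | None = None,
    data_type: str | None = None,
    target: str | None = None,
) -> list[SampleRecord]:
    """Conjunctive filter over model / data_type / target, order-stable.

    Model matching goes through :func:`normalize_model`, so ``Eu-myc``
    finds rows transcribed as ``Eμ-myc``.
    """
    out = records
    if model is not None:
        want = normalize_model(model)
        out = [r for r in out if r.model_alias == want]
    if data_type is not None:
        out = [r for r in out if r.data_type == data_type]
    if target is not None:
        out = [r for r in out if r.target == target]
    return list(out)


def write_validation_report(issues: list[ValidationIssue], path) -> None:
    with open(path, "w") as fh:
        fh.write("severity\tsample_id\tmessage\n")
        for issue in issues:
            fh.write(f"{issue}\n")
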