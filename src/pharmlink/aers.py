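"""Parsing of AERS-style quarterly report files and drug profile construction.

The FDA adverse event reporting system publishes quarterly dumps in which
each report (identified by an ISR number) is spread over several delimited
text files: a DRUG file listing the medications with their suspect role
codes (PS = primary suspect, SS = secondary suspect, C = concomitant,
I = interacting), and a REAC file listing the reported side-effect
keywords.  This module joins the two on the report ID, applies the
role-code and keyword-frequency filters, and builds drug side-effect
profiles in two flavours:

* ``freq`` -- each keyword coded by its reporting frequency for the drug,
* ``bit``  -- each keyword coded 1/0 by presence in any report of the drug.

Drug identifiers are treated as opaque strings; an optional two-column
synonym map can collapse reported names onto canonical IDs.  No name
normalisation beyond that is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: default column names of the `$`-delimited AERS dialect
DRUG_COLUMNS = {"isr": "ISR", "drug": "DRUGNAME", "role": "ROLE_COD"}
REAC_COLUMNS = {"isr": "ISR", "keyword": "PT"}


@dataclass
class DrugEntry:
    drug_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown role code {self.role!r}")


@dataclass
class Report:
    report_id: str
    drugs: list[DrugEntry]
    keywords: set[str]


@dataclass
class ReportSet:
    """A collection of joined adverse-event reports.

    ``parse_log`` counts reports dropped for appearing in only one file and
    malformed lines skipped during parsing.
    """

    reports: list[Report]
    parse_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate report IDs in ReportSet")

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def drug_ids(self) -> list[str]:
        """Sorted list of distinct drug IDs over all reports."""
        return sorted({e.drug_id for r in self.reports for e in r.drugs})


@dataclass
class KeywordVocabulary:
    """Retained side-effect keywords with their reporting statistics.

    ``d`` holds, for each retained keyword, the fraction of reports that
    mention it (report count / total report count); ``sigma`` is the mean
    of those fractions over the retained keywords and ``h`` the bandwidth
    parameter of the similarity weight function.
    """

    keywords: list[str]
    report_counts: np.ndarray
    d: np.ndarray
    sigma: float
    h: float
    n_reports: int

    @property
    def K(self) -> int:
        return len(self.keywords)

    def index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.keywords)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("keyword\treport_count\td_k\n")
            for k, c, d in zip(self.keywords, self.report_counts, self.d):
                fh.write(f"{k}\t{int(c)}\t{d:.10g}\n")


@dataclass
class PharmProfileMatrix:
    """Drugs x keywords profile matrix, frequency-valued or binary."""

    drug_ids: list[str]
    keywords: list[str]
    values: np.ndarray
    mode: str  # "freq" or "bit"

    def __post_init__(self) -> None:
        if self.mode not in ("freq", "bit"):
            raise ValueError(f"mode must be 'freq' or 'bit', got {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.keywords)):
            raise ValueError("values shape does not match drug/keyword lists")

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_ids.index(drug_id)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\t" + "\t".join(self.keywords) + "\n")
            for did, row in zip(self.drug_ids, self.values):
                fh.write(did + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "bit") -> "PharmProfileMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            keywords = header[1:]
            drug_ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                drug_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(drug_ids, keywords, np.array(rows, dtype=float), mode)


def _normalize_keyword(kw: str) -> str:
    return kw.strip().lower()


def _read_delimited(
    path: str | Path,
    columns: dict[str, str],
    delimiter: str,
    log: dict[str, int],
) -> list[dict[str, str]]:
    """Read one AERS-dialect file into records keyed by logical column name.

    Malformed lines (wrong field count, missing required fields) are skipped
    with a warning and counted in ``log``.
    """
    path = Path(path)
    try:
        fh = open(path)
    except OSError as exc:
        raise OSError(f"cannot read AERS file {path}: {exc}") from exc
    with fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"AERS file {path} is empty")
        header = [h.strip() for h in header_line.rstrip("\n").split(delimiter)]
        try:
            idx = {logical: header.index(name) for logical, name in columns.items()}
        except ValueError as exc:
            raise ValueError(f"missing column in {path}: {exc}") from exc
        records = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(delimiter)
            if len(parts) != len(header):
                logger.warning("%s:%d: malformed line skipped", path, lineno)
                log["malformed_lines"] = log.get("malformed_lines", 0) + 1
                continue
            rec = {logical: parts[i].strip() for logical, i in idx.items()}
            if any(not v for v in rec.values()):
                logger.warning("%s:%d: empty field, line skipped", path, lineno)
                log["malformed_lines"] = log.get("malformed_lines", 0) + 1
                continue
            records.append(rec)
    return records


def parse_quarter(
    drug_file: str | Path,
    reac_file: str | Path,
    delimiter: str = "$",
    drug_columns: dict[str, str] | None = None,
    reac_columns: dict[str, str] | None = None,
    synonym_map: dict[str, str] | None = None,
) -> ReportSet:
    """Parse one quarterly DRUG/REAC file pair into a :class:`ReportSet`.

    Records are inner-joined on the report ID: reports present in only one
    of the two files are dropped and counted in ``parse_log``.  Drug entries
    with role codes outside {PS, SS, C, I} are skipped with a warning.
    """
    log: dict[str, int] = {}
    drug_recs = _read_delimited(
        drug_file, drug_columns or DRUG_COLUMNS, delimiter, log
    )
    reac_recs = _read_delimited(
        reac_file, reac_columns or REAC_COLUMNS, delimiter, log
    )

    drugs_by_isr: dict[str, list[DrugEntry]] = {}
    for rec in drug_recs:
        role = rec["role"].upper()
        if role not in ROLE_CODES:
            logger.warning("unknown role code %r for report %s", role, rec["isr"])
            log["bad_role"] = log.get("bad_role", 0) + 1
            continue
        name = rec["drug"]
        if synonym_map:
            name = synonym_map.get(name, name)
        drugs_by_isr.setdefault(rec["isr"], []).append(DrugEntry(name, role))

    keywords_by_isr: dict[str, set[str]] = {}
    for rec in reac_recs:
        keywords_by_isr.setdefault(rec["isr"], set()).add(
            _normalize_keyword(rec["keyword"])
        )

    common = set(drugs_by_isr) & set(keywords_by_isr)
    log["dropped_drug_only"] = len(set(drugs_by_isr) - common)
    log["dropped_reac_only"] = len(set(keywords_by_isr) - common)

    reports = [
        Report(isr, drugs_by_isr[isr], keywords_by_isr[isr])
        for isr in sorted(common)
    ]
    return ReportSet(reports, log)


def merge_report_sets(report_sets: list[ReportSet]) -> ReportSet:
    """Concatenate quarters; report IDs must be globally unique."""
    reports: list[Report] = []
    log: dict[str, int] = {}
    for rs in report_sets:
        reports.extend(rs.reports)
        for k, v in rs.parse_log.items():
            log[k] = log.get(k, 0) + v
    return ReportSet(reports, log)


def filter_suspect_drugs(reports: ReportSet) -> ReportSet:
    """Keep only PS/SS drug entries; drop reports left with no drugs."""
    kept = []
    for r in reports.reports:
        entries = [e for e in r.drugs if e.role in ("PS", "SS")]
        if entries:
            kept.append(Report(r.report_id, entries, r.keywords))
    return ReportSet(kept, dict(reports.parse_log))


def build_vocabulary(
    reports: ReportSet,
    max_freq: float = 0.001,
    min_reports: int = 5,
    h: float = 1.0,
) -> KeywordVocabulary:
    """Build the retained keyword vocabulary under the frequency filters.

    A keyword's frequency d_k is the number of reports mentioning it divided
    by the total number of reports.  Keywords that appear too frequently
    (d_k > ``max_freq``) or too rarely (report count < ``min_reports``) are
    removed.  ``sigma`` is the mean of d_k over the *retained* keywords.
    """
    if len(reports) == 0:
        raise ValueError("cannot build a vocabulary from an empty ReportSet")
    n = len(reports)
    counts: dict[str, int] = {}
    for r in reports.reports:
        for kw in r.keywords:
            counts[kw] = counts.get(kw, 0) + 1

    retained = sorted(
        kw
        for kw, c in counts.items()
        if c >= min_reports and c / n <= max_freq
    )
    if not retained:
        raise ValueError(
            "no keywords retained; relax max_freq/min_reports "
            f"(max_freq={max_freq}, min_reports={min_reports}, "
            f"n_reports={n})"
        )
    cvec = np.array([counts[kw] for kw in retained], dtype=float)
    d = cvec / n
    return KeywordVocabulary(
        keywords=retained,
        report_counts=cvec,
        d=d,
        sigma=float(d.mean()),
        h=float(h),
        n_reports=n,
    )


def build_profiles(
    reports: ReportSet,
    vocab: KeywordVocabulary,
    mode: str = "freq",
    denominator: str = "drug",
) -> PharmProfileMatrix:
    """Build the drugs x keywords profile matrix.

    mode="bit" sets entry 1 iff the drug co-occurs with the keyword in at
    least one report.  mode="freq" sets the co-occurrence frequency: by
    default the count of reports containing both the drug and the keyword
    divided by the count of reports containing the drug
    (``denominator="drug"``); ``denominator="global"`` divides by the total
    report count instead.
    """
    if mode not in ("freq", "bit"):
        raise ValueError(f"mode must be 'freq' or 'bit', got {mode!r}")
    if denominator not in ("drug", "global"):
        raise ValueError("denominator must be 'drug' or 'global'")
    kw_idx = vocab.index()
    drug_ids = sorted(
        {e.drug_id for r in reports.reports for e in r.drugs if e.role in ("PS", "SS")}
    )
    drug_idx = {d: i for i, d in enumerate(drug_ids)}
    co = np.zeros((len(drug_ids), vocab.K))
    drug_report_count = np.zeros(len(drug_ids))
    for r in reports.reports:
        cols = [kw_idx[kw] for kw in r.keywords if kw in kw_idx]
        # count each drug once per report even if it has both PS and SS entries
        for did in {e.drug_id for e in r.drugs if e.role in ("PS", "SS")}:
            i = drug_idx[did]
            drug_report_count[i] += 1
            co[i, cols] += 1
    if mode == "bit":
        values = (co > 0).astype(float)
    elif denominator == "drug":
        denom = np.where(drug_report_count > 0, drug_report_count, 1.0)
        values = co / denom[:, None]
    else:
        values = co / float(len(reports))
    for i, did in enumerate(drug_ids):
        if not values[i].any():
            logger.info("drug %s has no retained keywords; zero profile", did)
    return PharmProfileMatrix(drug_ids, list(vocab.keywords), values, mode)


def vocabulary_from_profiles(
    profiles: PharmProfileMatrix, h: float = 1.0
) -> KeywordVocabulary:
    """Derive keyword statistics from an externally supplied profile matrix.

    For package-insert style resources (SIDER/JAPIC dialects) no report
    stream exists, so a keyword's frequency is taken as the fraction of
    drugs listing it.  Keywords listed by no drug are dropped.
    """
    present = profiles.values > 0
    counts = present.sum(axis=0).astype(float)
    keep = counts > 0
    if not keep.any():
        raise ValueError("profile matrix has no non-zero keywords")
    keywords = [k for k, m in zip(profiles.keywords, keep) if m]
    counts = counts[keep]
    d = counts / len(profiles.drug_ids)
    return KeywordVocabulary(
        keywords=keywords,
        report_counts=counts,
        d=d,
        sigma=float(d.mean()),
        h=float(h),
        n_reports=len(profiles.drug_ids),
    )


def restrict_profiles(
    profiles: PharmProfileMatrix, vocab: KeywordVocabulary
) -> PharmProfileMatrix:
    """Project a profile matrix onto a vocabulary's keyword order."""
    idx = {k: i for i, k in enumerate(profiles.keywords)}
    cols = [idx[k] for k in vocab.keywords if k in idx]
    kws = [k for k in vocab.keywords if k in idx]
    if kws != vocab.keywords:
        raise ValueError("profiles lack keywords present in the vocabulary")
    return PharmProfileMatrix(
        list(profiles.drug_ids), kws, profiles.values[:, cols], profiles.mode
    )


def write_quarter(
    reports: ReportSet,
    drug_file: str | Path,
    reac_file: str | Path,
    delimiter: str = "$",
) -> None:
    """Serialize a ReportSet back to the DRUG/REAC delimited dialect."""
    with open(drug_file, "w") as fh:
        fh.write(delimiter.join(["ISR", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"]) + "\n")
        for r in reports.reports:
            for seq, e in enumerate(r.drugs, start=1):
                fh.write(
                    delimiter.join([r.report_id, str(seq), e.role, e.drug_id]) + "\n"
                )
    with open(reac_file, "w") as fh:
        fh.write(delimiter.join(["ISR", "PT"]) + "\n")
        for r in reports.reports:
            for kw in sorted(r.keywords):
                fh.write(delimiter.join([r.report_id, kw]) + "\n")


def read_synonym_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (reported_name, canonical_id) synonym map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, canonical = line.rstrip("\n").split(delimiter)[:2]
            mapping[name] = canonical
    return mapping
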