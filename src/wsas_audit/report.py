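"""The audit report: descriptives + association + interchangeability tables.

Serializes to JSON (canonical, full precision, round-trips field-for-field),
flat CSV, and markdown.  Coefficients and p-values are printed to 4 decimal
places in the human-readable formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .descriptives import MedianComparison, SummaryStats
from .model import COMBINED, ItemId, ValidationReport
from .resampling import ResampleResult

_FMT = "{:.4f}"


def _label_display(label: str) -> str:
    if label == COMBINED:
        return "Combined"
    return ItemId(label).display_name


def _resample_to_dict(r: ResampleResult) -> dict:
    return {
        "label": r.label,
        "statistic": r.statistic,
        "observed": r.observed,
        "p_value": r.p_value,
        "n_resamples": r.n_resamples,
        "n_as_extreme": r.n_as_extreme,
        "tail": r.tail,
        "p_convention": r.p_convention,
        "seed": r.seed,
        "exact": r.exact,
    }


def _resample_from_dict(d: dict) -> ResampleResult:
    return ResampleResult(**d)


def _summary_to_dict(s: SummaryStats) -> dict:
    return {
        "item": s.item.value,
        "rating_kind": s.rating_kind,
        "n": s.n,
        "mean": s.mean,
        "median": s.median,
        "q1": s.q1,
        "q3": s.q3,
        "iqr": s.iqr,
        "min": s.min,
        "max": s.max,
        "skewness": s.skewness,
        "counts_by_level": list(s.counts_by_level),
    }


def _summary_from_dict(d: dict) -> SummaryStats:
    d = dict(d)
    d.pop("iqr", None)
    d["item"] = ItemId(d["item"])
    d["counts_by_level"] = tuple(d["counts_by_level"])
    return SummaryStats(**d)


@dataclass
class AuditReport:
    """Everything one audit run produced, in fixed report order."""

    validation: ValidationReport
    descriptives: list[SummaryStats]
    median_comparisons: list[MedianComparison]
    association: list[ResampleResult]
    interchangeability: list[ResampleResult]
    alpha: float
    config: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "validation": {
                "n_records": self.validation.n_records,
                "n_out_of_range": self.validation.n_out_of_range,
                "n_duplicates": self.validation.n_duplicates,
                "n_missing": self.validation.n_missing,
                "strict_pass": self.validation.strict_pass,
            },
            "descriptives": [_summary_to_dict(s) for s in self.descriptives],
            "median_comparisons": [
                {
                    "item": m.item.value,
                    "impaired_median": m.impaired_median,
                    "bothered_median": m.bothered_median,
                    "differs": m.differs,
                    "higher": m.higher,
                }
                for m in self.median_comparisons
            ],
            "association": [_resample_to_dict(r) for r in self.association],
            "interchangeability": [
                {**_resample_to_dict(r), "reject": r.p_value <= self.alpha}
                for r in self.interchangeability
            ],
            "alpha": self.alpha,
            "config": self.config,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuditReport":
        v = d["validation"]
        return cls(
            validation=ValidationReport(
                v["n_records"], v["n_out_of_range"], v["n_duplicates"], v["n_missing"]
            ),
            descriptives=[_summary_from_dict(s) for s in d["descriptives"]],
            median_comparisons=[
                MedianComparison(
                    ItemId(m["item"]), m["impaired_median"], m["bothered_median"]
                )
                for m in d["median_comparisons"]
            ],
            association=[_resample_from_dict(r) for r in d["association"]],
            interchangeability=[
                _resample_from_dict({k: v for k, v in r.items() if k != "reject"})
                for r in d["interchangeability"]
            ],
            alpha=d["alpha"],
            config=d.get("config", {}),
            version=d.get("version", ""),
            timestamp=d.get("timestamp", ""),
        )

    # -- human-readable formats ------------------------------------------

    def to_markdown(self) -> str:
        lines = ["# Impaired vs bothered ratings audit", ""]
        lines += [
            f"Records: {self.validation.n_records}; strict validation "
            f"{'passed' if self.validation.strict_pass else 'FAILED'}.",
            "",
            "## Association (Spearman rho, permutation test)",
            "",
            "| Ratings | Correlation coefficient | p | Exact |",
            "|---|---|---|---|",
        ]
        for r in self.association:
            lines.append(
                f"| {_label_display(r.label)} | {_FMT.format(r.observed)} | "
                f"{_FMT.format(r.p_value)} | {'yes' if r.exact else 'no'} |"
            )
        lines += [
            "",
            "## Interchangeability (sign-flip resampling)",
            "",
            f"| Ratings | Mean difference | p | Reject at alpha={self.alpha:g} |",
            "|---|---|---|---|",
        ]
        for r in self.interchangeability:
            lines.append(
                f"| {_label_display(r.label)} | {_FMT.format(r.observed)} | "
                f"{_FMT.format(r.p_value)} | {'yes' if r.p_value <= self.alpha else 'no'} |"
            )
        lines += ["", "## Descriptives", "", "| Item | Kind | n | Mean | Median | Q1 | Q3 | IQR |",
                  "|---|---|---|---|---|---|---|---|"]
        for s in self.descriptives:
            lines.append(
                f"| {s.item.display_name} | {s.rating_kind} | {s.n} | "
                f"{_FMT.format(s.mean)} | {s.median:g} | {s.q1:g} | {s.q3:g} | {s.iqr:g} |"
            )
        lines.append("")
        return "\n".join(lines)

    def to_csv(self) -> str:
        rows = ["section,label,statistic,value,p_value,n_resamples,exact"]
        for r in self.association:
            rows.append(
                f"association,{_label_display(r.label)},{r.statistic},"
                f"{_FMT.format(r.observed)},{_FMT.format(r.p_value)},"
                f"{r.n_resamples},{r.exact}"
            )
        for r in self.interchangeability:
            rows.append(
                f"interchangeability,{_label_display(r.label)},{r.statistic},"
                f"{_FMT.format(r.observed)},{_FMT.format(r.p_value)},"
                f"{r.n_resamples},{r.exact}"
            )
        for s in self.descriptives:
            rows.append(
                f"descriptives,{s.item.display_name},{s.rating_kind}_mean,"
                f"{_FMT.format(s.mean)},,,"
            )
            rows.append(
                f"descriptives,{s.item.display_name},{s.rating_kind}_median,"
                f"{s.median:g},,,"
            )
        return "\n".join(rows) + "\n"


def write_report(report: AuditReport, path, format: str = "json") -> None:
    """Serialize an audit report as JSON (canonical), CSV or markdown."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif format == "csv":
        path.write_text(report.to_csv())
    elif format == "markdown":
        path.write_text(report.to_markdown())
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> AuditReport:
    """Read back a JSON report written by :func:`write_report`."""
    return AuditReport.from_dict(json.loads(Path(path).read_text()))
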