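"""Long-format cohort container shared by all analysis stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: columns every cohort table must carry, in canonical order
CORE_COLUMNS = ["subject_id", "visit_index", "age", "sex", "site_id", "study_id"]

CROSS_SECTIONAL = "cross-sectional"
LONGITUDINAL = "longitudinal"

#: a study with fewer longitudinal subjects than this is demoted to
#: cross-sectional (baseline rows only)
MIN_LONGITUDINAL_SUBJECTS = 3


@dataclass
class CohortTable:
    """Long-format observations with design metadata.

    ``data`` holds one row per (subject, visit); ``visit_index`` is 0-based
    with 0 the baseline.  ``design`` is ``cross-sectional`` (exactly one row
    per subject) or ``longitudinal``.
    """

    data: pd.DataFrame
    design: str = LONGITUDINAL
    covariates: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.data.duplicated(["subject_id", "visit_index"]).any():
            raise ValueError("(subject_id, visit_index) must be unique")
        if self.design not in (CROSS_SECTIONAL, LONGITUDINAL):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == CROSS_SECTIONAL:
            if (self.data.groupby("subject_id").size() > 1).any():
                raise ValueError("cross-sectional design requires one row per subject")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def n_longitudinal_subjects(self) -> int:
        return int((self.data.groupby("subject_id").size() > 1).sum())

    def baseline(self) -> pd.DataFrame:
        """One row per subject at its lowest visit index."""
        d = self.data.sort_values(["subject_id", "visit_index"])
        return d.groupby("subject_id", as_index=False).first()

    def apply_curation_rule(self) -> "CohortTable":
        """Demote to cross-sectional when too few subjects have repeat visits.

        A table with fewer than :data:`MIN_LONGITUDINAL_SUBJECTS` subjects
        having more than one visit is reduced to its baseline rows.
        """
        if (
            self.design == LONGITUDINAL
            and self.n_longitudinal_subjects() < MIN_LONGITUDINAL_SUBJECTS
        ):
            return CohortTable(
                self.baseline().reset_index(drop=True),
                design=CROSS_SECTIONAL,
                covariates=list(self.covariates),
                outcomes=list(self.outcomes),
            )
        return self

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write the table as CSV plus a sidecar ``<stem>.meta.json``."""
        path = Path(path)
        extra = [
            c for c in self.data.columns if c not in CORE_COLUMNS
        ]
        self.data[CORE_COLUMNS + extra].to_csv(path, index=False)
        meta = {
            "design": self.design,
            "covariates": self.covariates,
            "outcomes": self.outcomes,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            data,
            design=meta.get("design", LONGITUDINAL),
            covariates=meta.get("covariates", []),
            outcomes=meta.get("outcomes", []),
        )
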