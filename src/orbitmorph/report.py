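"""Pydantic schema for the end-to-end pipeline report.

The report mirrors the structure of the published result tables — type
distribution, per-type descriptives, the ANOVA / Kruskal-Wallis table,
rule accuracies and derived cut-offs — so diffing a run against printed
values is mechanical.  ``orbitmorph/schemas/report.schema.json`` is the
JSON-Schema export of :class:`PipelineReport` shipped with the package;
``validate_report`` checks a report dictionary against the model.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field


class RunMeta(BaseModel):
    seed: int
    n: int
    package_version: str
    source: str  # "simulated" or the input path


class TypeCount(BaseModel):
    type: str
    count: int = Field(ge=0)
    prevalence: float = Field(ge=0.0, le=1.0)


class DescriptiveCell(BaseModel):
    type: str
    dimension: str
    mean: float
    sd: float = Field(ge=0.0)
    min: float
    max: float
    n: int = Field(ge=1)


class GroupTestRow(BaseModel):
    dimension: str
    anova_f: float
    anova_df: Tuple[int, int]
    anova_p: float = Field(ge=0.0, le=1.0)
    eta_squared: float = Field(ge=0.0, le=1.0)
    kruskal_h: float
    kruskal_p: float = Field(ge=0.0, le=1.0)


class Metrics(BaseModel):
    labels: List[str]
    confusion: List[List[int]]
    accuracy: float = Field(ge=0.0, le=1.0)
    precision: Dict[str, float]
    recall: Dict[str, float]
    n: int = Field(ge=1)
    ci: Optional[Tuple[float, float]] = None


class DerivationSection(BaseModel):
    model_config = ConfigDict(protected_namespaces=())

    standardization_means: List[float]
    standardization_sds: List[float]
    centroids_standardized: List[List[float]]
    centroids_raw: List[List[float]]
    cluster_to_type: Dict[str, str]
    cv_accuracy_mean: float = Field(ge=0.0, le=1.0)
    cv_accuracy_sd: float = Field(ge=0.0)
    h_cut: float
    d_cut: float
    tree_accuracy: float = Field(ge=0.0, le=1.0)
    d1: float
    d2: float
    d1_ci: Tuple[float, float]
    d2_ci: Tuple[float, float]
    depth_accuracy: float = Field(ge=0.0, le=1.0)


class PipelineReport(BaseModel):
    """Everything one seeded end-to-end run produces."""

    meta: RunMeta
    type_distribution: List[TypeCount]
    descriptives: List[DescriptiveCell]
    group_tests: List[GroupTestRow]
    derivation: DerivationSection
    classification: Dict[str, Metrics]
    warnings: List[str] = Field(default_factory=list)


def validate_report(report: dict) -> PipelineReport:
    """Validate a report dictionary; raises pydantic.ValidationError."""
    return PipelineReport.model_validate(report)


def shipped_schema() -> dict:
    """The JSON schema bundled with the installed package."""
    text = resources.files("orbitmorph").joinpath("schemas/report.schema.json").read_text()
    return json.loads(text)
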