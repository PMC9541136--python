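"""The risk-of-bias assessment document.

A 17-question structured form in two parts: a research statement / pre-bias
section (target population, inferential goal, provenance, cleaning), then
the bias assessment proper — a resolution statement followed by three
questions (representativeness, temporal consistency, mitigation) for each of
the geographic, environmental and taxonomic domains plus an "other biases"
triple.  The tool records answers and attaches quantitative evidence; it
never judges content.  Bias flagging is an explicit boolean set by the
assessor, because the judgement is qualitative and tied to an inferential
goal, not a score.

Assessments are versioned: each iteration is a deep copy with an incremented
version, a parent link and a recorded reason, so the full chain can be
published alongside the study.  Serialization is deterministic YAML —
serialize -> parse -> serialize is byte-identical.
"""

from __future__ import annotations

import copy
import datetime as _dt
import html as _html
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .core import TargetPopulation
from .io import ProvenanceLog

__all__ = [
    "Question",
    "Assessment",
    "ValidationReport",
    "new_assessment",
    "set_resolution_statement",
    "attach_evidence",
    "set_answer",
    "flag_bias",
    "validate",
    "next_iteration",
    "serialize",
    "parse",
    "render",
    "SECTION_ORDER",
]

SECTION_ORDER = (
    "research_statement",
    "resolution",
    "geographic",
    "environmental",
    "taxonomic",
    "other",
)
_EXPECTED_SECTION_COUNTS = {
    "research_statement": 4,
    "resolution": 1,
    "geographic": 3,
    "environmental": 3,
    "taxonomic": 3,
    "other": 3,
}
_N_QUESTIONS = 17

RELEVANT = "relevant"
NOT_RELEVANT = "not_relevant_with_justification"


@dataclass
class Question:
    id: str
    section: str
    role: str
    prompt: str
    answer: str = ""
    relevance: str = RELEVANT
    justification: str = ""
    bias_flagged: bool = False
    evidence: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "section": self.section,
            "role": self.role,
            "prompt": self.prompt,
            "answer": self.answer,
            "relevance": self.relevance,
            "justification": self.justification,
            "bias_flagged": self.bias_flagged,
            "evidence": list(self.evidence),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Question":
        return cls(
            id=str(d["id"]),
            section=str(d["section"]),
            role=str(d["role"]),
            prompt=str(d["prompt"]),
            answer=str(d.get("answer", "")),
            relevance=str(d.get("relevance", RELEVANT)),
            justification=str(d.get("justification", "")),
            bias_flagged=bool(d.get("bias_flagged", False)),
            evidence=[str(e) for e in d.get("evidence", [])],
        )


def _load_prompts() -> list[dict]:
    text = resources.files("robitt").joinpath("data/questions.yaml").read_text("utf-8")
    items = yaml.safe_load(text)
    return items


def _check_schema(questions: list[Question]) -> None:
    if len(questions) != _N_QUESTIONS:
        raise ValueError(f"assessment must hold exactly {_N_QUESTIONS} questions, got {len(questions)}")
    ids = [q.id for q in questions]
    if len(set(ids)) != len(ids):
        raise ValueError("question ids must be unique")
    counts: dict[str, int] = {}
    for q in questions:
        counts[q.section] = counts.get(q.section, 0) + 1
    if counts != _EXPECTED_SECTION_COUNTS:
        raise ValueError(f"section counts {counts} != required {_EXPECTED_SECTION_COUNTS}")


@dataclass
class Assessment:
    population: TargetPopulation
    questions: list[Question]
    version: int = 1
    parent_version: int | None = None
    created: str = ""
    resolution_statement: dict | None = None
    provenance: ProvenanceLog | None = None
    artifacts: dict[str, str] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_schema(self.questions)
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    def question(self, qid: str) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise KeyError(f"no question with id {qid!r}")

    def register_artifact(self, ref: str, path: str) -> None:
        """Make a heuristic output attachable as evidence."""
        self.artifacts[ref] = str(path)


def new_assessment(pop: TargetPopulation, created: str = "") -> Assessment:
    """Fresh version-1 template with all 17 prompts and empty answers."""
    questions = [Question.from_dict(d) for d in _load_prompts()]
    return Assessment(population=pop, questions=questions, version=1, created=created)


def set_answer(
    assessment: Assessment,
    qid: str,
    answer: str,
    relevance: str = RELEVANT,
    justification: str = "",
) -> Assessment:
    q = assessment.question(qid)
    if relevance not in (RELEVANT, NOT_RELEVANT):
        raise ValueError(f"unknown relevance {relevance!r}")
    q.answer = answer
    q.relevance = relevance
    q.justification = justification
    return assessment


def flag_bias(assessment: Assessment, qid: str, flagged: bool = True) -> Assessment:
    """Record the assessor's explicit judgement that a question reveals bias."""
    q = assessment.question(qid)
    if q.role not in ("representativeness", "temporal_consistency", "other_bias"):
        raise ValueError(f"question {qid} ({q.role}) does not carry a bias flag")
    q.bias_flagged = bool(flagged)
    return assessment


def set_resolution_statement(
    assessment: Assessment,
    spatial_resolution: float,
    temporal_resolution: int,
    taxonomic_rank: str = "species",
) -> Assessment:
    """Declare the grain sizes at which the assessment itself is conducted.

    These default into every heuristic invocation.  A mismatch with the
    population's declared inference grain is surfaced as a prominent warning
    by :func:`validate` (a screen at decadal/100 km grain says little about
    yearly/1 km inference) but is never an error.
    """
    if not spatial_resolution > 0 or temporal_resolution < 1:
        raise ValueError("resolutions must be positive")
    assessment.resolution_statement = {
        "spatial_resolution": float(spatial_resolution),
        "temporal_resolution": int(temporal_resolution),
        "taxonomic_rank": str(taxonomic_rank),
    }
    return assessment


def attach_evidence(assessment: Assessment, qid: str, ref: str) -> Assessment:
    """Attach a registered heuristic artifact to a question (deduplicated)."""
    q = assessment.question(qid)
    if ref not in assessment.artifacts:
        raise KeyError(f"artifact ref {ref!r} is not registered on this assessment")
    if ref not in q.evidence:
        q.evidence.append(ref)
    return assessment


@dataclass(frozen=True)
class ValidationReport:
    unanswered: tuple[str, ...]
    violations: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def clean(self) -> bool:
        return not (self.unanswered or self.violations or self.warnings)


def validate(assessment: Assessment) -> ValidationReport:
    """Completeness check: pure, idempotent, never judges answer content.

    Reports unanswered questions and subsections where a bias flag is set but
    the mitigation answer is empty and no not-relevant justification exists.
    """
    unanswered = tuple(
        q.id for q in assessment.questions if q.relevance == RELEVANT and not q.answer.strip()
    )
    violations = []
    for section in ("geographic", "environmental", "taxonomic", "other"):
        qs = [q for q in assessment.questions if q.section == section]
        flagged = any(q.bias_flagged for q in qs)
        if not flagged:
            continue
        mitigation = next(q for q in qs if q.role == "mitigation")
        excused = mitigation.relevance == NOT_RELEVANT and mitigation.justification.strip()
        if not mitigation.answer.strip() and not excused:
            violations.append(
                f"bias flagged in the {section} subsection but mitigation question "
                f"{mitigation.id} is unanswered and no not-relevant justification is given"
            )
    warnings = []
    rs = assessment.resolution_statement
    if rs is None:
        warnings.append("no resolution statement: assessment grain sizes are undeclared")
    else:
        pop = assessment.population
        if (
            rs["spatial_resolution"] != pop.spatial_resolution
            or rs["temporal_resolution"] != pop.temporal_resolution
        ):
            warnings.append(
                "assessment grain ({sr}°, {tr} yr) differs from the declared inference grain "
                "({psr}°, {ptr} yr): conclusions about bias at the assessment grain may not "
                "transfer to the inference grain".format(
                    sr=rs["spatial_resolution"], tr=rs["temporal_resolution"],
                    psr=pop.spatial_resolution, ptr=pop.temporal_resolution,
                )
            )
    return ValidationReport(tuple(unanswered), tuple(violations), tuple(warnings))


def _population_diff(old: TargetPopulation, new: TargetPopulation) -> list[str]:
    diffs = []
    a, b = old.to_dict(), new.to_dict()
    for key in a:
        if a[key] != b[key]:
            diffs.append(f"{key}: {a[key]!r} -> {b[key]!r}")
    return diffs


def next_iteration(
    assessment: Assessment,
    reason: str,
    population: TargetPopulation | None = None,
    created: str = "",
) -> Assessment:
    """New version of the assessment; the prior version stays untouched.

    Redefining the target population between iterations (the usual reason:
    shrinking the extent to the adequately sampled portion) is recorded as an
    explicit diff in the history entry.
    """
    new = copy.deepcopy(assessment)
    changes: list[str] = []
    if population is not None:
        changes = _population_diff(assessment.population, population)
        new.population = population
    new.parent_version = assessment.version
    new.version = assessment.version + 1
    new.created = created or _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    new.history = list(assessment.history) + [
        {
            "version": new.version,
            "parent_version": assessment.version,
            "reason": reason,
            "created": new.created,
            "population_changes": changes,
        }
    ]
    return new


# ---------------------------------------------------------------------------
# serialization (deterministic YAML)

def _canonical_dict(assessment: Assessment) -> dict:
    return {
        "robitt_assessment": {
            "version": assessment.version,
            "parent_version": assessment.parent_version,
            "created": assessment.created,
            "target_population": assessment.population.to_dict(),
            "resolution_statement": assessment.resolution_statement,
            "provenance": assessment.provenance.to_dict() if assessment.provenance else None,
            "artifacts": {k: assessment.artifacts[k] for k in sorted(assessment.artifacts)},
            "questions": [q.to_dict() for q in assessment.questions],
            "history": [dict(h) for h in assessment.history],
        }
    }


def serialize(assessment: Assessment) -> str:
    """Deterministic, human-diffable YAML; round-trips byte-identically."""
    return yaml.safe_dump(
        _canonical_dict(assessment),
        sort_keys=False,
        default_flow_style=False,
        allow_unicode=True,
        width=88,
    )


def parse(text: str) -> Assessment:
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "robitt_assessment" not in doc:
        raise ValueError("not an assessment document")
    d = doc["robitt_assessment"]
    pop_d = dict(d["target_population"])
    pop = TargetPopulation(
        geo_extent=_wkt(pop_d["geo_extent_wkt"]),
        temporal_extent=tuple(pop_d["temporal_extent"]),
        taxa=tuple(pop_d["taxa"]),
        spatial_resolution=pop_d["spatial_resolution"],
        temporal_resolution=pop_d["temporal_resolution"],
        env_axes=tuple(pop_d.get("env_axes", ())),
        grid_origin=tuple(pop_d.get("grid_origin", (-180.0, -90.0))),
    )
    a = Assessment(
        population=pop,
        questions=[Question.from_dict(q) for q in d["questions"]],
        version=int(d["version"]),
        parent_version=d.get("parent_version"),
        created=str(d.get("created", "")),
        resolution_statement=d.get("resolution_statement"),
        provenance=ProvenanceLog.from_dict(d["provenance"]) if d.get("provenance") else None,
        artifacts=dict(d.get("artifacts", {})),
        history=[dict(h) for h in d.get("history", [])],
    )
    return a


def _wkt(text: str):
    from shapely import wkt as _shapely_wkt

    return _shapely_wkt.loads(text)


def save(assessment: Assessment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(assessment))


def load(path) -> Assessment:
    with open(path, "r", encoding="utf-8") as fh:
        return parse(fh.read())


# ---------------------------------------------------------------------------
# rendering

_SECTION_TITLES = {
    "research_statement": "Research statement and pre-bias assessment",
    "resolution": "Assessment resolution statement",
    "geographic": "Geographic biases",
    "environmental": "Environmental biases",
    "taxonomic": "Taxonomic biases",
    "other": "Other potential biases",
}


def _render_markdown(a: Assessment) -> str:
    lines: list[str] = []
    lines.append(f"# Risk-of-bias assessment (version {a.version})")
    lines.append("")
    pop = a.population.to_dict()
    lines.append("## Target population")
    lines.append("")
    lines.append(f"- Geographic extent (WKT): `{pop['geo_extent_wkt']}`")
    lines.append(f"- Temporal extent: {pop['temporal_extent'][0]}–{pop['temporal_extent'][1]}")
    lines.append(f"- Target taxa: {', '.join(pop['taxa'])}")
    lines.append(
        f"- Inference grain: {pop['spatial_resolution']}° cells, "
        f"{pop['temporal_resolution']}-year periods"
    )
    if pop["env_axes"]:
        lines.append(f"- Environmental axes: {', '.join(pop['env_axes'])}")
    lines.append("")
    if a.resolution_statement:
        rs = a.resolution_statement
        lines.append(
            f"Assessment grain: {rs['spatial_resolution']}° cells, "
            f"{rs['temporal_resolution']}-year periods, rank {rs['taxonomic_rank']}."
        )
        lines.append("")
    if a.provenance:
        lines.append("## Data provenance and cleaning")
        lines.append("")
        p = a.provenance
        lines.append(f"- Input records: {p.input_count}")
        for s in p.steps:
            lines.append(f"- {s['rule']}: removed {s['removed']} ({s['description']})")
        lines.append(f"- Records retained: {p.output_count}")
        if p.sources:
            lines.append(f"- Sources: {'; '.join(p.sources)}")
        lines.append("")
    for section in SECTION_ORDER:
        lines.append(f"## {_SECTION_TITLES[section]}")
        lines.append("")
        for q in (q for q in a.questions if q.section == section):
            lines.append(f"### {q.id} {q.prompt}")
            lines.append("")
            if q.relevance == NOT_RELEVANT:
                lines.append(f"*Not relevant:* {q.justification or '(no justification given)'}")
            else:
                lines.append(q.answer if q.answer.strip() else "*(unanswered)*")
            if q.bias_flagged:
                lines.append("")
                lines.append("**Potential bias flagged by the assessor.**")
            if q.evidence:
                lines.append("")
                lines.append("Evidence:")
                for ref in q.evidence:
                    lines.append(f"- {ref}: `{a.artifacts.get(ref, '(unregistered)')}`")
            lines.append("")
    lines.append("## Version history")
    lines.append("")
    if a.history:
        for h in reversed(a.history):  # newest first
            lines.append(f"- v{h['version']} (from v{h['parent_version']}, {h['created']}): {h['reason']}")
            for c in h.get("population_changes", []):
                lines.append(f"  - population change — {c}")
    else:
        lines.append("- v1 (initial assessment)")
    lines.append("")
    return "\n".join(lines)


def _render_html(a: Assessment) -> str:
    md = _render_markdown(a)
    body: list[str] = []
    in_list = False
    for line in md.split("\n"):
        if line.startswith("- ") or line.startswith("  - "):
            if not in_list:
                body.append("<ul>")
                in_list = True
            body.append(f"<li>{_html.escape(line.lstrip('- ').lstrip())}</li>")
            continue
        if in_list:
            body.append("</ul>")
            in_list = False
        if line.startswith("### "):
            body.append(f"<h3>{_html.escape(line[4:])}</h3>")
        elif line.startswith("## "):
            body.append(f"<h2>{_html.escape(line[3:])}</h2>")
        elif line.startswith("# "):
            body.append(f"<h1>{_html.escape(line[2:])}</h1>")
        elif line.strip():
            body.append(f"<p>{_html.escape(line)}</p>")
    if in_list:
        body.append("</ul>")
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        "<title>Risk-of-bias assessment</title></head>\n<body>\n"
        + "\n".join(body)
        + "\n</body></html>\n"
    )


def render(assessment: Assessment, fmt: str = "markdown") -> str:
    """Render the document with deterministic section ordering."""
    if fmt == "markdown":
        return _render_markdown(assessment)
    if fmt == "html":
        return _render_html(assessment)
    raise ValueError(f"unknown render format {fmt!r} (expected 'markdown' or 'html')")
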