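"""Candidate-list filter cascades, domain-dependency calls and the core complex.

The multi-bait interactome is distilled into candidate lists by a cascade of
set-logic rules: intersection of significant hits across full-length bait
experiments, subtraction of hits also significant with the free
biotin-ligase (eYFP) control (with explicit allowlist overrides and
unconditional denylist removals), replicate-evidence and fold-change
requirements, a curation rule retaining proteins with a literature link to
mRNA metabolism or a domain-specific interaction, and finally the strict
intersection over bait experiments that defines the core complex. Every
decision about every protein is recorded in a :class:`FilterTrace` so each
exclusion is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .lfq_io import CurationTable, LfqMatrix, write_table

if TYPE_CHECKING:  # pragma: no cover
    from .volcano import VolcanoTable

__all__ = [
    "FilterTrace",
    "DomainCall",
    "CLASS_ORDER",
    "significant_at_least",
    "intersect_significant",
    "subtract_control",
    "curation_filter",
    "replicate_evidence_filter",
    "fold_change_filter",
    "domain_dependency_map",
    "core_complex",
    "high_confidence_cascade",
    "write_traces",
]

#: canonical ordering of significance classes, strongest evidence first
CLASS_ORDER = ("SigA", "SigB", "SigC")


@dataclass
class FilterTrace:
    """Audit record for one protein: every rule applied and its outcome."""

    protein_id: str
    records: list[tuple[str, str, bool]] = field(default_factory=list)
    overrides: list[str] = field(default_factory=list)

    def add(self, rule: str, detail: str, passed: bool) -> "FilterTrace":
        self.records.append((rule, detail, passed))
        return self

    def override(self, rule: str, detail: str) -> "FilterTrace":
        """Record an allowlist override that flips a failing rule to pass."""
        self.overrides.append(f"{rule}: {detail}")
        self.records.append((rule, f"OVERRIDE {detail}", True))
        return self

    @property
    def passed(self) -> bool:
        return all(ok for _, _, ok in self.records)

    @property
    def failing_rules(self) -> list[str]:
        return [rule for rule, _, ok in self.records if not ok]


def _merge_traces(
    into: dict[str, FilterTrace], new: Iterable[FilterTrace]
) -> dict[str, FilterTrace]:
    for trace in new:
        if trace.protein_id in into:
            into[trace.protein_id].records.extend(trace.records)
            into[trace.protein_id].overrides.extend(trace.overrides)
        else:
            into[trace.protein_id] = trace
    return into


# ---------------------------------------------------------------------------
# significance set logic
# ---------------------------------------------------------------------------

def significant_at_least(table: "VolcanoTable", min_class: str) -> set[str]:
    """Proteins significant at ``min_class`` or any stronger class (enriched side).

    "At least SigB" therefore means the union of SigA and SigB calls.
    """
    if min_class not in CLASS_ORDER:
        raise KeyError(f"unknown class {min_class!r}")
    chosen = CLASS_ORDER[: CLASS_ORDER.index(min_class) + 1]
    out: set[str] = set()
    for name in chosen:
        if name in table.cutoffs:
            out |= table.significant(name)
    return out


def intersect_significant(
    tables: Mapping[str, "VolcanoTable"], min_class: str
) -> set[str]:
    """Proteins meeting ``min_class`` (or stronger) in every listed experiment."""
    if not tables:
        raise ValueError("empty table map")
    sets = [significant_at_least(t, min_class) for t in tables.values()]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def subtract_control(
    candidates: Iterable[str],
    control: "VolcanoTable",
    classes: Sequence[str] = ("SigA", "SigB"),
    curation: CurationTable | None = None,
) -> tuple[set[str], dict[str, FilterTrace]]:
    """Remove candidates also significant with the free-ligase control.

    A candidate significant in the control at any of ``classes`` is dropped
    unless its curation allowlist flag is set, in which case it is retained
    with the override recorded. Denylisted proteins (recurrent contaminants
    seen across unrelated bait experiments) are removed unconditionally.
    """
    curation = curation or CurationTable()
    control_hits: set[str] = set()
    for name in classes:
        if name in control.cutoffs:
            control_hits |= control.significant(name)

    kept: set[str] = set()
    traces: dict[str, FilterTrace] = {}
    for pid in sorted(set(candidates)):
        flags = curation.get(pid)
        trace = FilterTrace(pid)
        if flags.denylist:
            trace.add("denylist", "flagged as recurrent contaminant", False)
        elif pid in control_hits:
            if flags.allowlist:
                trace.override(
                    "control_subtraction",
                    "significant in eYFP control but allowlisted",
                )
            else:
                trace.add(
                    "control_subtraction",
                    f"significant in eYFP control ({'/'.join(classes)})",
                    False,
                )
        else:
            trace.add("control_subtraction", "absent from eYFP control classes", True)
        if trace.passed:
            kept.add(pid)
        traces[pid] = trace
    return kept, traces


def curation_filter(
    candidates: Iterable[str],
    curation: CurationTable,
    domain_calls: Mapping[str, "DomainCall"],
) -> tuple[set[str], dict[str, FilterTrace]]:
    """Keep candidates with an mRNA-metabolism link or a terminal-domain-specific interaction.

    A protein passes if its curated ``mrna_metabolism`` flag is set, or if
    its domain-dependency call indicates it is absent from at least one bait
    truncation (dependency other than ``catalytic``/``unresolved``).
    """
    kept: set[str] = set()
    traces: dict[str, FilterTrace] = {}
    for pid in sorted(set(candidates)):
        flags = curation.get(pid)
        call = domain_calls.get(pid)
        dependency = call.dependency if call is not None else "unresolved"
        domain_specific = dependency not in ("catalytic", "unresolved")
        ok = flags.mrna_metabolism or domain_specific
        trace = FilterTrace(pid).add(
            "curation",
            f"mrna_metabolism={flags.mrna_metabolism} dependency={dependency}",
            ok,
        )
        if ok:
            kept.add(pid)
        traces[pid] = trace
    return kept, traces


def replicate_evidence_filter(
    matrix: LfqMatrix,
    samples: Sequence[str],
    min_count: int,
) -> tuple[set[str], dict[str, FilterTrace]]:
    """Keep proteins observed in at least ``min_count`` of ``samples``.

    Counts use observed (never imputed) quantifications only, e.g. "in at
    least two of three bait replicates".
    """
    if min_count > len(samples):
        raise ValueError(
            f"min_count {min_count} exceeds the {len(samples)} replicates in scope"
        )
    counts = matrix.observed_counts(samples)
    kept: set[str] = set()
    traces: dict[str, FilterTrace] = {}
    for pid in matrix.protein_ids:
        ok = int(counts[pid]) >= min_count
        traces[pid] = FilterTrace(pid).add(
            "replicate_evidence",
            f"{int(counts[pid])}/{len(samples)} replicates, need >= {min_count}",
            ok,
        )
        if ok:
            kept.add(pid)
    return kept, traces


def fold_change_filter(
    table: "VolcanoTable",
    threshold: float,
) -> tuple[set[str], dict[str, FilterTrace]]:
    """Keep proteins enriched at least ``threshold``-fold (boundary inclusive).

    The exclusion is of proteins *less than* ``threshold``-fold enriched, so
    a ratio exactly at the threshold passes.
    """
    if threshold <= 0:
        raise ValueError("fold-change threshold must be positive")
    kept: set[str] = set()
    traces: dict[str, FilterTrace] = {}
    for pid, ratio in table.data["ratio"].items():
        ok = bool(ratio >= threshold)
        traces[pid] = FilterTrace(pid).add(
            "fold_change", f"ratio {ratio:.3g}, need >= {threshold}", ok
        )
        if ok:
            kept.add(pid)
    return kept, traces


# ---------------------------------------------------------------------------
# domain dependency
# ---------------------------------------------------------------------------

#: bait keys used in domain-dependency maps: full-length (endogenous and/or
#: overexpressed), N-terminal truncation, C-terminal truncation, catalytic core
FL, DELTA_N, DELTA_C, CAT = "FL", "dN", "dC", "cat"


@dataclass(frozen=True)
class DomainCall:
    """Which bait-domain configuration a prey's significance pattern implies."""

    protein_id: str
    classes: Mapping[str, str | None]
    dependency: str


def domain_dependency_map(
    protein_id: str,
    classes: Mapping[str, str | None],
    min_class: str = "SigB",
) -> DomainCall:
    """Infer which bait domain an interaction depends on.

    ``classes`` maps bait keys (``FL``, ``dN``, ``dC``, ``cat``; an ``FL``
    entry may also be given as ``FL_endo``/``FL_oe``, in which case all given
    full-length entries must be significant) to the protein's significance
    class with that bait, or ``None``. Mixed classes at or above ``min_class``
    all count as significant. Rules:

    - significant with every truncation including the catalytic core ->
      ``catalytic`` (binds the catalytic domain);
    - significant with FL and the N-terminal truncation but neither the
      C-terminal truncation nor the core -> ``C-terminal``;
    - significant with FL and the C-terminal truncation but neither the
      N-terminal truncation nor the core -> ``N-terminal``;
    - significant with FL and both single truncations but not the core ->
      ``both-termini``;
    - anything else -> ``unresolved``.
    """
    allowed = set(CLASS_ORDER[: CLASS_ORDER.index(min_class) + 1])

    def sig(key: str) -> bool:
        return classes.get(key) in allowed

    fl_keys = [k for k in classes if k == FL or k.startswith("FL_")]
    if not fl_keys:
        raise ValueError("domain call requires a full-length (FL) entry")
    fl = all(sig(k) for k in fl_keys)

    if sig(CAT) and sig(DELTA_N) and sig(DELTA_C):
        dependency = "catalytic"
    elif fl and sig(DELTA_N) and not sig(DELTA_C) and not sig(CAT):
        dependency = "C-terminal"
    elif fl and sig(DELTA_C) and not sig(DELTA_N) and not sig(CAT):
        dependency = "N-terminal"
    elif fl and sig(DELTA_N) and sig(DELTA_C) and not sig(CAT):
        dependency = "both-termini"
    else:
        dependency = "unresolved"
    return DomainCall(protein_id=protein_id, classes=dict(classes), dependency=dependency)


# ---------------------------------------------------------------------------
# core complex and the full cascade
# ---------------------------------------------------------------------------

def core_complex(candidate_sets: Mapping[str, Iterable[str]]) -> set[str]:
    """Strict intersection over bait experiments: proteins found with every bait."""
    if not candidate_sets:
        raise ValueError("empty candidate-set map")
    if len(candidate_sets) < 2:
        raise ValueError("core complex needs candidate sets from at least 2 experiments")
    sets = [set(s) for s in candidate_sets.values()]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def high_confidence_cascade(
    fl_tables: Mapping[str, "VolcanoTable"],
    control: "VolcanoTable",
    curation: CurationTable,
    domain_calls: Mapping[str, DomainCall] | None = None,
    min_class: str = "SigB",
    control_classes: Sequence[str] = ("SigA", "SigB"),
) -> tuple[set[str], dict[str, FilterTrace]]:
    """The three-rule high-confidence cascade.

    (i) significant at ``min_class`` or better in every full-length bait
    experiment; (ii) not significant with the free-ligase control (allowlist
    overrides, denylist removals); (iii) curated mRNA-metabolism link or a
    domain-specific interaction. When no domain calls are supplied rule (iii)
    falls back to the curation flag alone.
    """
    traces: dict[str, FilterTrace] = {}
    step1 = intersect_significant(fl_tables, min_class)
    universe = set().union(*(set(t.data.index) for t in fl_tables.values()))
    for pid in sorted(universe):
        traces[pid] = FilterTrace(pid).add(
            "intersect_significant",
            f"at least {min_class} in all of {sorted(fl_tables)}",
            pid in step1,
        )
    step2, t2 = subtract_control(step1, control, control_classes, curation)
    _merge_traces(traces, t2.values())
    step3, t3 = curation_filter(step2, curation, domain_calls or {})
    _merge_traces(traces, t3.values())
    return step3, traces


def write_traces(traces: Mapping[str, FilterTrace], path) -> None:
    """Write a machine-readable FilterTrace log as a TSV."""
    rows = []
    for pid in sorted(traces):
        trace = traces[pid]
        for rule, detail, ok in trace.records:
            rows.append(
                {
                    "protein_id": pid,
                    "rule": rule,
                    "detail": detail,
                    "passed": ok,
                    "final_status": trace.passed,
                }
            )
    write_table(pd.DataFrame(rows), path, index=False)
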