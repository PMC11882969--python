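"""Hit-picking funnel for ultra-large docking campaigns.

Implements the post-docking triage used to pick synthesis candidates from a
ranked score table: property windowing (350-500 Da, cLogP 3-5), score-ordered
leader clustering at ECFP4 Tc 0.5 with the best-scoring member as cluster
representative, a novelty exclusion against known cannabinoid-receptor
ligands (max Tc >= 0.36 removed), a polar-contact pose filter at the
receptor's anchor residues, and Tc >= 0.5 analog expansion around chosen
hits.  The output is an explicit manual-review export: automation stops
where visual inspection starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .chem import (
    CLOGP_ESTIMATOR,
    DEFAULT_FP_BITS,
    DEFAULT_FP_RADIUS,
    bulk_tanimoto,
    compute_ecfp4,
    tanimoto,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "TriageConfig",
    "TriageError",
    "TriageReport",
    "analog_search",
    "leader_cluster",
    "novelty_filter",
    "property_filter",
    "run_funnel",
]


class TriageError(ValueError):
    pass


@dataclass
class MoleculeRecord:
    """One library molecule with its computed properties and docking score.

    ``dock_score`` follows docking convention: lower (more negative) is
    better.  ``cluster_id`` is filled by :func:`leader_cluster`.
    """

    id: str
    smiles: str
    mw: float | None = None
    clogp: float | None = None
    fingerprint: ExplicitBitVect | None = None
    dock_score: float = float("nan")
    cluster_id: int | None = None
    clogp_estimator: str = CLOGP_ESTIMATOR
    # planted truth carried by the synthetic generator; None on real data
    true_cluster: int | None = None
    known_like: bool | None = None
    scaffold: str | None = None

    def with_fingerprint(self, n_bits: int, radius: int) -> "MoleculeRecord":
        return replace(
            self, fingerprint=compute_ecfp4(self.smiles, n_bits, radius, self.id)
        )


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the campaign funnel (defaults follow the CB1R screen)."""

    mw_range: tuple[float, float] = (350.0, 500.0)
    clogp_range: tuple[float, float] = (3.0, 5.0)
    top_n: int = 300_000
    cluster_tc: float = 0.5
    novelty_tc: float = 0.36
    analog_tc: float = 0.5
    fingerprint_bits: int = DEFAULT_FP_BITS
    fingerprint_radius: int = DEFAULT_FP_RADIUS

    def __post_init__(self):
        for name in ("cluster_tc", "novelty_tc", "analog_tc"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise TriageError(f"{name} must be in (0, 1], got {v}")
        if self.top_n < 1:
            raise TriageError(f"top_n must be >= 1, got {self.top_n}")


def property_filter(
    molecules: list[MoleculeRecord], config: TriageConfig
) -> list[MoleculeRecord]:
    """Retain molecules inside the MW and cLogP windows (bounds inclusive).

    Records with a missing property are rejected with a logged reason.
    Input order is preserved.
    """
    lo_mw, hi_mw = config.mw_range
    lo_lp, hi_lp = config.clogp_range
    kept = []
    for m in molecules:
        if m.mw is None or m.clogp is None or np.isnan(m.mw) or np.isnan(m.clogp):
            logger.warning("property_filter: %s rejected (missing property)", m.id)
            continue
        if lo_mw <= m.mw <= hi_mw and lo_lp <= m.clogp <= hi_lp:
            kept.append(m)
    return kept


def leader_cluster(
    ranked: list[MoleculeRecord], tc_threshold: float
) -> list[MoleculeRecord]:
    """Single-pass leader clustering of a best-score-first ranked list.

    Each molecule joins the first existing leader with Tc >= threshold,
    otherwise it founds a new cluster.  Because the input is sorted, the
    leader is automatically the best-scoring member of its cluster.  Note
    that leaders are *not* guaranteed to be pairwise below the threshold;
    single-pass leader clustering does not provide that property.

    Returns new records with ``cluster_id`` assigned (leader order).
    Raises if the input is not sorted by ascending dock score (sorting is
    the caller's contract, so silent resorting would hide ranking bugs).
    """
    scores = [m.dock_score for m in ranked]
    if any(b < a for a, b in zip(scores, scores[1:])):
        raise TriageError("leader_cluster input must be sorted best-score-first")
    for m in ranked:
        if m.fingerprint is None:
            raise TriageError(f"molecule {m.id} has no fingerprint")
    leaders: list[ExplicitBitVect] = []
    out = []
    for m in ranked:
        cid = None
        if leaders:
            sims = bulk_tanimoto(m.fingerprint, leaders)
            for j, s in enumerate(sims):
                if s >= tc_threshold:
                    cid = j
                    break
        if cid is None:
            cid = len(leaders)
            leaders.append(m.fingerprint)
        out.append(replace(m, cluster_id=cid))
    return out


def cluster_representatives(clustered: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """First (= best-scoring) member of each cluster, in cluster order."""
    seen: dict[int, MoleculeRecord] = {}
    for m in clustered:
        if m.cluster_id not in seen:
            seen[m.cluster_id] = m
    return [seen[c] for c in sorted(seen)]


def novelty_filter(
    candidates: list[MoleculeRecord],
    reference_fps: list[ExplicitBitVect],
    novelty_tc: float,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Drop candidates resembling known ligands.

    A candidate whose *maximum* Tc against the reference set is >= the
    novelty threshold is removed.  Returns (survivors, report) where the
    report holds each candidate's nearest-reference Tc.  An empty reference
    set is an error — it is not the same statement as "keep everything".
    """
    if not reference_fps:
        raise TriageError("novelty_filter requires a non-empty reference set")
    rows, kept = [], []
    for m in candidates:
        if m.fingerprint is None:
            raise TriageError(f"molecule {m.id} has no fingerprint")
        nearest = max(bulk_tanimoto(m.fingerprint, reference_fps))
        novel = nearest < novelty_tc
        rows.append({"id": m.id, "nearest_reference_tc": nearest, "novel": novel})
        if novel:
            kept.append(m)
    return kept, pd.DataFrame(rows)


def analog_search(
    query: MoleculeRecord, library: list[MoleculeRecord], analog_tc: float
) -> list[tuple[MoleculeRecord, float]]:
    """Library members with Tc(query) >= threshold, most similar first.

    Ties are broken by id so that results are stable across runs.
    """
    if query.fingerprint is None:
        raise TriageError(f"query {query.id} has no fingerprint")
    hits = []
    for m in library:
        if m.fingerprint is None:
            raise TriageError(f"molecule {m.id} has no fingerprint")
        tc = tanimoto(query.fingerprint, m.fingerprint)
        if tc >= analog_tc:
            hits.append((m, tc))
    hits.sort(key=lambda mt: (-mt[1], mt[0].id))
    return hits


@dataclass
class TriageReport:
    """Per-stage survivor counts plus the final ranked candidate list."""

    stage_counts: dict[str, int]
    candidates: pd.DataFrame
    novelty_report: pd.DataFrame
    contact_report: pd.DataFrame
    config: TriageConfig = field(repr=False, default=TriageConfig())

    def counts_non_increasing(self) -> bool:
        vals = list(self.stage_counts.values())
        return all(b <= a for a, b in zip(vals, vals[1:]))

    def write(self, outdir: str | Path, stem: str = "triage") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.candidates.to_csv(outdir / f"{stem}_candidates.csv", index=False)
        self.novelty_report.to_csv(outdir / f"{stem}_novelty.csv", index=False)
        self.contact_report.to_csv(outdir / f"{stem}_contacts.csv", index=False)
        payload = {
            "stage_counts": self.stage_counts,
            "thresholds": {
                "top_n": self.config.top_n,
                "cluster_tc": self.config.cluster_tc,
                "novelty_tc": self.config.novelty_tc,
                "mw_range": list(self.config.mw_range),
                "clogp_range": list(self.config.clogp_range),
            },
        }
        (outdir / f"{stem}_report.json").write_text(json.dumps(payload, indent=2))


def run_funnel(
    score_table: pd.DataFrame,
    library: dict[str, MoleculeRecord],
    reference_fps: list[ExplicitBitVect],
    poses: dict[str, "LigandPose"],  # noqa: F821 - see pose module
    site: "BindingSiteSpec",  # noqa: F821
    config: TriageConfig,
) -> TriageReport:
    """The campaign funnel on one score table.

    Stages, in order: top-N selection by score -> leader clustering ->
    cluster representatives -> novelty exclusion -> polar-contact pose
    filter.  The survivor count can only decrease from stage to stage.
    Score ties are broken stably by id.
    """
    from .pose import polar_contact_filter  # local import to avoid a cycle

    if not {"id", "score"} <= set(score_table.columns):
        raise TriageError("score table needs columns id,score")
    orphans = [i for i in score_table["id"] if i not in library]
    if orphans:
        raise TriageError(f"score table ids missing from library: {orphans[:10]}")

    counts: dict[str, int] = {"scored": len(score_table)}
    ranked_ids = (
        score_table.sort_values(["score", "id"], kind="mergesort")["id"].tolist()
    )
    top = ranked_ids[: config.top_n]
    counts["top_n"] = len(top)

    mols = []
    score_of = dict(zip(score_table["id"], score_table["score"]))
    for i in top:
        m = library[i]
        if m.fingerprint is None:
            m = m.with_fingerprint(config.fingerprint_bits, config.fingerprint_radius)
        mols.append(replace(m, dock_score=float(score_of[i])))

    clustered = leader_cluster(mols, config.cluster_tc)
    reps = cluster_representatives(clustered)
    counts["cluster_representatives"] = len(reps)

    novel, novelty_report = novelty_filter(reps, reference_fps, config.novelty_tc)
    counts["novel"] = len(novel)

    contact_rows, survivors = [], []
    pose_orphans = [m.id for m in novel if m.id not in poses]
    if pose_orphans:
        raise TriageError(f"poses missing for candidates: {pose_orphans[:10]}")
    for m in novel:
        res = polar_contact_filter(poses[m.id], site)
        contact_rows.append(
            {
                "id": m.id,
                "passed": res.passed,
                "n_contacts": len(res.contacts),
                "min_distance": min((c.distance for c in res.contacts), default=np.nan),
                "reason": res.reason,
            }
        )
        if res.passed:
            survivors.append(m)
    counts["polar_contact"] = len(survivors)

    cand = pd.DataFrame(
        {
            "id": [m.id for m in survivors],
            "smiles": [m.smiles for m in survivors],
            "dock_score": [m.dock_score for m in survivors],
            "cluster_id": [m.cluster_id for m in survivors],
            "mw": [m.mw for m in survivors],
            "clogp": [m.clogp for m in survivors],
        }
    ).sort_values(["dock_score", "id"], kind="mergesort").reset_index(drop=True)
    return TriageReport(
        stage_counts=counts,
        candidates=cand,
        novelty_report=novelty_report,
        contact_report=pd.DataFrame(contact_rows),
        config=config,
    )
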