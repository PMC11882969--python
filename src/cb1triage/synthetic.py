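"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its spec: the same spec produces
byte-identical output, and the planted ground truth (cluster labels,
known-like flags, contact labels, true curve and PK parameters) is always
returned alongside the data so that downstream recovery tests never have to
re-derive the truth from the data itself.

The chemical library generator assembles molecules from the frozen fragment
grammar (:mod:`cb1triage.grammar`): one scaffold per planted chemotype
cluster, decorated with up to two substituents, members admitted greedily
only while every pair inside the cluster keeps ECFP4 Tc >= 0.5 and the
molecule stays inside the property window.  Impossible requests (more
clusters than scaffolds, cluster sizes beyond what the grammar supports)
fail loudly rather than silently relaxing the similarity structure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import grammar
from .chem import bulk_tanimoto, compute_ecfp4, mol_props, tanimoto
from .pharm import ConcResponse, _logistic
from .pk import PKProfile
from .pose import BindingSiteSpec, LigandPose
from .triage import MoleculeRecord

__all__ = [
    "CurveSpec",
    "GenerationError",
    "LibrarySpec",
    "PKSpec",
    "PoseSet",
    "SyntheticCurve",
    "SyntheticLibrary",
    "SyntheticPK",
    "gen_conc_response",
    "gen_library",
    "gen_pk_profile",
    "gen_poses",
]

#: margin kept between planted cross-cluster similarity and the novelty cutoff
NOVELTY_CUTOFF = 0.36
INTRA_CLUSTER_TC = 0.5


class GenerationError(ValueError):
    pass


# --------------------------------------------------------------------------
# chemical library


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a synthetic ranked docking library with planted structure."""

    n_molecules: int
    n_chemotype_clusters: int
    fraction_knownlike: float = 0.0
    mw_range: tuple[float, float] = (350.0, 500.0)
    clogp_range: tuple[float, float] = (3.0, 5.0)
    seed: int = 0
    score_mean: float = -35.0
    score_sd: float = 4.0

    def __post_init__(self):
        if not self.n_molecules >= self.n_chemotype_clusters >= 1:
            raise GenerationError(
                "need n_molecules >= n_chemotype_clusters >= 1, got "
                f"{self.n_molecules} / {self.n_chemotype_clusters}"
            )
        if not 0.0 <= self.fraction_knownlike <= 1.0:
            raise GenerationError("fraction_knownlike must be in [0, 1]")


@lru_cache(maxsize=64)
def _scaffold_members(
    scaffold: str,
    mw_range: tuple[float, float],
    clogp_range: tuple[float, float],
    intra_tc: float = INTRA_CLUSTER_TC,
) -> tuple[tuple[str, float, float], ...]:
    """Greedy in-window member list for one scaffold, in admission order.

    Candidates are every substituent combination that parses and lands in
    the property window, canonicalized and deduplicated.  The lead member
    is the lexicographically smallest canonical SMILES; remaining
    candidates are visited in order of decreasing similarity to the lead
    and admitted only if their Tc to *every* already-admitted member stays
    at or above ``intra_tc``.  Deterministic by construction — no RNG.
    """
    cands: dict[str, tuple[float, float]] = {}
    for r1 in grammar.SUBSTITUENTS:
        for r2 in grammar.SUBSTITUENTS:
            smi = grammar.instantiate(scaffold, r1, r2)
            try:
                mw, clogp = mol_props(smi)
            except ValueError:
                continue
            if mw_range[0] <= mw <= mw_range[1] and clogp_range[0] <= clogp <= clogp_range[1]:
                from rdkit import Chem

                cands[Chem.CanonSmiles(smi)] = (mw, clogp)
    if not cands:
        return ()
    smis = sorted(cands)
    fps = [compute_ecfp4(s) for s in smis]
    lead = fps[0]
    order = sorted(
        range(len(smis)), key=lambda i: (-tanimoto(lead, fps[i]), smis[i])
    )
    chosen: list[int] = []
    chosen_fps = []
    for i in order:
        if not chosen or min(bulk_tanimoto(fps[i], chosen_fps)) >= intra_tc:
            chosen.append(i)
            chosen_fps.append(fps[i])
    return tuple((smis[i], *cands[smis[i]]) for i in chosen)


def _allocate(total: int, caps: list[int], what: str) -> list[int]:
    """Split ``total`` molecules over clusters as evenly as capacities allow.

    Water-filling: saturated clusters keep their capacity, the remainder is
    re-spread over the others; fails loudly when the grammar cannot supply
    the request at all.
    """
    if total > sum(caps):
        raise GenerationError(
            f"fragment grammar cannot supply {total} {what} molecules "
            f"across {len(caps)} clusters (short by {total - sum(caps)}); "
            "request fewer molecules or more clusters"
        )
    sizes = [0] * len(caps)
    remaining, active = total, list(range(len(caps)))
    while remaining:
        base, extra = divmod(remaining, len(active))
        quota = {i: base + (1 if j < extra else 0)
                 for j, i in enumerate(active)}
        saturated = [i for i in active if sizes[i] + quota[i] >= caps[i]]
        if not saturated:
            for i in active:
                sizes[i] += quota[i]
            remaining = 0
        else:
            for i in saturated:
                remaining -= caps[i] - sizes[i]
                sizes[i] = caps[i]
            active = [i for i in active if i not in saturated]
    return sizes


@dataclass
class SyntheticLibrary:
    """A generated library plus its planted ground truth."""

    spec: LibrarySpec
    records: list[MoleculeRecord]
    reference_ligands: list[MoleculeRecord]
    grammar_version: str = grammar.GRAMMAR_VERSION

    @property
    def reference_fps(self):
        return [m.fingerprint for m in self.reference_ligands]

    def score_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": [m.id for m in self.records],
             "score": [m.dock_score for m in self.records]}
        )

    def ranked(self) -> list[MoleculeRecord]:
        return sorted(self.records, key=lambda m: (m.dock_score, m.id))

    def true_cluster_count(self) -> int:
        return len({m.true_cluster for m in self.records})

    def knownlike_ids(self) -> set[str]:
        return {m.id for m in self.records if m.known_like}

    def write_smi(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.records:
                fh.write(f"{m.smiles} {m.id}\n")

    def write_score_csv(self, path: str | Path) -> None:
        self.score_table().to_csv(path, index=False)


def gen_library(spec: LibrarySpec) -> SyntheticLibrary:
    """Generate a ranked docking library with planted chemotype clusters.

    Cluster k is built on the k-th grammar scaffold; a ``fraction_knownlike``
    subset of molecules is built on the reference-ligand scaffolds instead,
    forming its own clusters that a novelty filter at Tc >= 0.36 must
    remove.  Docking scores are drawn independently of cluster membership,
    so the score ranking interleaves clusters.  Generation is verified:
    every novel molecule is checked to stay below the novelty cutoff
    against the reference ligands, and every cluster is checked against the
    other clusters' lead members.
    """
    n, k = spec.n_molecules, spec.n_chemotype_clusters
    n_known = round(spec.fraction_knownlike * n)
    ref_names = list(grammar.REFERENCE_SCAFFOLDS)
    novel_names = list(grammar.NOVEL_SCAFFOLDS)

    k_known = 0 if n_known == 0 else min(max(1, round(spec.fraction_knownlike * k)),
                                         len(ref_names))
    k_novel = k - k_known
    n_novel = n - n_known
    if k_novel > len(novel_names):
        raise GenerationError(
            f"grammar has {len(novel_names)} novel scaffolds; cannot plant "
            f"{k_novel} novel clusters"
        )
    if n_novel > 0 and k_novel == 0:
        raise GenerationError(
            "fraction_knownlike leaves novel molecules but no novel cluster"
        )
    if n_known > 0 and k_known == 0:
        raise GenerationError("known-like molecules requested but no cluster for them")
    if n_known < k_known or n_novel < k_novel:
        raise GenerationError(
            "fraction_knownlike and n_chemotype_clusters are incompatible: "
            f"{n_known} known-like molecules for {k_known} clusters, "
            f"{n_novel} novel molecules for {k_novel} clusters"
        )

    window = (spec.mw_range, spec.clogp_range)
    ref_members = {s: _scaffold_members(grammar.REFERENCE_SCAFFOLDS[s], *window)
                   for s in ref_names}
    for s in ref_names:
        if not ref_members[s]:
            raise GenerationError(f"reference scaffold {s} has no in-window members")

    # reference ligands: lead member of every reference scaffold
    reference_ligands = []
    for s in ref_names:
        smi, mw, clogp = ref_members[s][0]
        reference_ligands.append(
            MoleculeRecord(id=f"REF-{s}", smiles=smi, mw=mw, clogp=clogp,
                           fingerprint=compute_ecfp4(smi), scaffold=s)
        )
    ref_fps = [m.fingerprint for m in reference_ligands]

    plan: list[tuple[str, bool, int]] = []  # (scaffold, known_like, size)
    if k_known:
        caps = [len(ref_members[s]) for s in ref_names[:k_known]]
        sizes = _allocate(n_known, caps, "known-like")
        plan += [(s, True, sz) for s, sz in zip(ref_names, sizes)]
    if k_novel:
        novel_sets = {s: _scaffold_members(grammar.NOVEL_SCAFFOLDS[s], *window)
                      for s in novel_names[:k_novel]}
        caps = [len(novel_sets[s]) for s in novel_names[:k_novel]]
        sizes = _allocate(n_novel, caps, "novel")
        plan += [(s, False, sz) for s, sz in zip(novel_names, sizes)]

    records: list[MoleculeRecord] = []
    cluster_leads: list = []
    for cluster_id, (scaffold_name, known, size) in enumerate(plan):
        members = (ref_members if known else novel_sets)[scaffold_name][:size]
        lead_fp = None
        for smi, mw, clogp in members:
            fp = compute_ecfp4(smi)
            if lead_fp is None:
                lead_fp = fp
            if known:
                own_ref = ref_fps[ref_names.index(scaffold_name)]
                if tanimoto(fp, own_ref) < NOVELTY_CUTOFF:
                    raise GenerationError(
                        f"known-like member of {scaffold_name} fell below the "
                        f"novelty cutoff vs its reference ligand"
                    )
            elif max(bulk_tanimoto(fp, ref_fps)) >= NOVELTY_CUTOFF:
                raise GenerationError(
                    f"novel member of {scaffold_name} reached the novelty "
                    f"cutoff against a reference ligand"
                )
            records.append(
                MoleculeRecord(
                    id="",  # assigned below
                    smiles=smi, mw=mw, clogp=clogp, fingerprint=fp,
                    true_cluster=cluster_id, known_like=known,
                    scaffold=scaffold_name,
                )
            )
        cluster_leads.append(lead_fp)

    # cross-cluster guarantee: no member may reach the clustering threshold
    # against another cluster's lead (and stays under the novelty margin)
    for m in records:
        sims = bulk_tanimoto(
            m.fingerprint,
            [f for c, f in enumerate(cluster_leads) if c != m.true_cluster],
        )
        if sims and max(sims) >= NOVELTY_CUTOFF:
            raise GenerationError(
                f"cross-cluster similarity {max(sims):.3f} >= {NOVELTY_CUTOFF} "
                f"for a member of {m.scaffold}; grammar guarantee violated"
            )

    rng = np.random.default_rng(spec.seed)
    scores = rng.normal(spec.score_mean, spec.score_sd, len(records))
    for i, (m, score) in enumerate(zip(records, scores)):
        m.id = f"SYN{i:05d}"
        m.dock_score = float(score)
    return SyntheticLibrary(spec=spec, records=records,
                            reference_ligands=reference_ligands)


# --------------------------------------------------------------------------
# docked poses with planted polar contacts


@dataclass
class PoseSet:
    poses: list[LigandPose]
    planted_ids: set[str]
    site: BindingSiteSpec


_POSE_ELEMENTS = ("C", "C", "C", "C", "C", "N", "O", "C", "S")


def gen_poses(
    n: int,
    planted_contact_fraction: float,
    site: BindingSiteSpec,
    seed: int = 0,
    ids: list[str] | None = None,
) -> PoseSet:
    """Synthetic ligand poses around a binding site.

    A ``planted_contact_fraction`` subset (chosen by the seeded RNG) gets
    one polar atom placed inside the contact cutoff of a randomly chosen
    anchor; all other poses keep every polar atom outside the cutoff of
    every anchor.  Pose ids match ``ids`` when given (e.g. a score table),
    else POSE00000....
    """
    if not 0.0 <= planted_contact_fraction <= 1.0:
        raise GenerationError("planted_contact_fraction must be in [0, 1]")
    if ids is not None and len(ids) != n:
        raise GenerationError("ids length must equal n")
    rng = np.random.default_rng(seed)
    anchors = site.anchor_coords
    center = anchors.mean(axis=0)
    cutoff = site.contact_cutoff

    n_planted = round(planted_contact_fraction * n)
    planted_idx = set(rng.choice(n, size=n_planted, replace=False).tolist())

    poses, planted_ids = [], set()
    for i in range(n):
        pid = ids[i] if ids is not None else f"POSE{i:05d}"
        n_atoms = int(rng.integers(8, 15))
        elements = [
            _POSE_ELEMENTS[j] for j in rng.integers(0, len(_POSE_ELEMENTS), n_atoms)
        ]
        elements[0] = "O" if rng.random() < 0.5 else "N"  # always >= 1 polar atom
        if i in planted_idx:
            coords = center + rng.normal(0.0, 1.5, (n_atoms, 3))
            a = anchors[rng.integers(0, len(anchors))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[0] = a + direction * (cutoff * rng.uniform(0.5, 0.95))
            # keep the remaining polar atoms wherever they fall: one contact
            # is sufficient and planted
            planted_ids.add(pid)
        else:
            for _ in range(200):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                blob = center + direction * (cutoff * 4.0 + 6.0)
                coords = blob + rng.normal(0.0, 1.5, (n_atoms, 3))
                polar = np.array([e in ("N", "O") for e in elements])
                from scipy.spatial.distance import cdist

                if cdist(coords[polar], anchors).min() > cutoff * 1.1:
                    break
            else:  # pragma: no cover - geometrically unreachable
                raise GenerationError("could not place a contact-free pose")
        poses.append(LigandPose(molecule_id=pid, elements=elements, coords=coords))
    return PoseSet(poses=poses, planted_ids=planted_ids, site=site)


def demo_binding_site(contact_cutoff: float = 3.5) -> BindingSiteSpec:
    """A three-anchor site mimicking the Ser/Thr/His anchor geometry."""
    from .pose import Anchor

    return BindingSiteSpec(
        anchors=(
            Anchor("S383:OG", (0.0, 0.0, 0.0)),
            Anchor("T201:OG1", (5.5, 1.0, -2.0)),
            Anchor("H178:NE2", (-3.0, 4.5, 2.5)),
        ),
        contact_cutoff=contact_cutoff,
    )


# --------------------------------------------------------------------------
# concentration-response curves


@dataclass(frozen=True)
class CurveSpec:
    """Truth for one synthetic 4PL concentration-response experiment."""

    true_ec50: float  # molar
    true_emax: float = 100.0  # % of control
    true_hill: float = 1.0
    baseline: float = 0.0  # %
    noise_sd: float = 0.0  # % (additive Gaussian on the % scale)
    n_concentrations: int = 8
    n_replicates: int = 3
    seed: int = 0
    conc_range: tuple[float, float] = (1e-12, 1e-5)  # molar

    def __post_init__(self):
        if self.true_ec50 <= 0:
            raise GenerationError("true_ec50 must be positive")
        if self.n_concentrations < 4:
            raise GenerationError("need >= 4 concentrations")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise GenerationError("need >= 1 replicate")


@dataclass
class SyntheticCurve:
    spec: CurveSpec
    data: ConcResponse

    def write_csv(self, path: str | Path, compound_id: str = "SYN-CPD") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["compound", "pathway", "conc_M", "response", "replicate"])
            for r in range(self.data.n_replicates):
                for c, y in zip(self.data.concentrations, self.data.responses[r]):
                    w.writerow([compound_id, self.data.pathway, f"{c:.6e}",
                                f"{y:.6f}", r + 1])


def gen_conc_response(
    spec: CurveSpec, compound_id: str = "SYN-CPD", pathway: str = "cAMP"
) -> SyntheticCurve:
    """Log-spaced 4PL responses with additive Gaussian noise on the % scale."""
    conc = np.logspace(
        np.log10(spec.conc_range[0]), np.log10(spec.conc_range[1]),
        spec.n_concentrations,
    )
    clean = _logistic(np.log10(conc), spec.baseline, spec.true_emax,
                      np.log10(spec.true_ec50), spec.true_hill)
    rng = np.random.default_rng(spec.seed)
    responses = clean[None, :] + rng.normal(
        0.0, spec.noise_sd, (spec.n_replicates, spec.n_concentrations)
    )
    data = ConcResponse(compound_id=compound_id, pathway=pathway,
                        concentrations=conc, responses=responses)
    return SyntheticCurve(spec=spec, data=data)


# --------------------------------------------------------------------------
# pharmacokinetic profiles


@dataclass(frozen=True)
class PKSpec:
    """One-compartment truth for a synthetic concentration-time profile."""

    dose: float  # mg/kg
    ka: float  # 1/min (absorption; ignored for bolus)
    ke: float  # 1/min (elimination)
    v_over_f: float  # mL/kg (apparent volume over bioavailability)
    lloq: float = 0.0  # ng/mL
    times: tuple[float, ...] = (5, 15, 30, 60, 120, 240, 360, 480, 1440)
    seed: int = 0
    route: str = "extravascular"
    noise_cv: float = 0.0  # lognormal CV on concentrations

    def __post_init__(self):
        if self.ke <= 0:
            raise GenerationError("ke must be positive")
        if self.route == "extravascular" and self.ka == self.ke:
            raise GenerationError("ka == ke degenerates the closed form")
        t = np.asarray(self.times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise GenerationError("times must be >= 0 and strictly increasing")
        if self.route not in ("bolus", "extravascular"):
            raise GenerationError(f"unknown route {self.route!r}")

    @property
    def true_auc_inf(self) -> float:
        """dose / (V/F * ke) in ng*min/mL (dose mg/kg -> ng/kg)."""
        return self.dose * 1e6 / (self.v_over_f * self.ke)

    @property
    def true_t_half(self) -> float:
        return float(np.log(2) / self.ke)

    def concentration(self, t: np.ndarray) -> np.ndarray:
        """Closed-form concentration (ng/mL) at times t (min)."""
        t = np.asarray(t, dtype=float)
        d = self.dose * 1e6  # ng per kg body weight
        if self.route == "bolus":
            return d / self.v_over_f * np.exp(-self.ke * t)
        return (d * self.ka / (self.v_over_f * (self.ka - self.ke))
                * (np.exp(-self.ke * t) - np.exp(-self.ka * t)))


@dataclass
class SyntheticPK:
    spec: PKSpec
    profile: PKProfile

    def write_csv(self, path: str | Path, animal_id: str = "M1") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["animal_id", "compartment", "time_min", "conc", "lloq"])
            for t, c in zip(self.profile.times, self.profile.concentrations):
                w.writerow([animal_id, self.profile.compartment, f"{t:g}",
                            f"{c:.6f}", f"{self.profile.lloq:g}"])


def gen_pk_profile(spec: PKSpec, compartment: str = "plasma") -> SyntheticPK:
    """Sample the closed-form profile at the spec's times.

    With ``noise_cv > 0`` concentrations get multiplicative lognormal noise.
    Below-LLOQ values are left in place — the NCA's LLOQ rules are the
    component under test, so censoring is not pre-applied here.
    """
    t = np.asarray(spec.times, dtype=float)
    conc = spec.concentration(t)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2))
        conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, conc.size)
    profile = PKProfile(compartment=compartment, times=t, concentrations=conc,
                        lloq=spec.lloq, route=spec.route)
    return SyntheticPK(spec=spec, profile=profile)
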