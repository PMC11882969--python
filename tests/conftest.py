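"""Shared fixtures: a small planted library, a binding site, oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from cb1triage.pose import LigandPose
from cb1triage.synthetic import LibrarySpec, demo_binding_site, gen_library

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library():
    """100 molecules in 5 planted clusters, 30 % known-like."""
    return gen_library(
        LibrarySpec(n_molecules=100, n_chemotype_clusters=5,
                    fraction_knownlike=0.3, seed=7)
    )


@pytest.fixture(scope="session")
def site():
    return demo_binding_site()


def brute_force_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Exhaustive minimum RMSD over all within-element atom permutations.

    Independent oracle for the assignment-based RMSD; only usable on small
    instances (the permutation count is the product of factorials of the
    element-class sizes).
    """
    classes = sorted(set(a.elements))
    idx_a = {e: [i for i, x in enumerate(a.elements) if x == e] for e in classes}
    idx_b = {e: [i for i, x in enumerate(b.elements) if x == e] for e in classes}
    best = np.inf
    per_class_perms = [
        list(itertools.permutations(idx_b[e])) for e in classes
    ]
    for combo in itertools.product(*per_class_perms):
        sq = 0.0
        for e, perm in zip(classes, combo):
            for i, j in zip(idx_a[e], perm):
                sq += ((a.coords[i] - b.coords[j]) ** 2).sum()
        best = min(best, sq)
    return float(np.sqrt(best / len(a.elements)))


@pytest.fixture(scope="session")
def rmsd_oracle():
    return brute_force_rmsd


def random_pose_pair(rng, elements=("C", "C", "C", "O", "O", "O", "N", "N"),
                     noise=0.8):
    """A pose and a perturbed, within-element-shuffled copy of it."""
    coords = rng.normal(0.0, 3.0, (len(elements), 3))
    a = LigandPose("a", list(elements), coords)
    perm = np.arange(len(elements))
    for e in set(elements):
        idx = [i for i, x in enumerate(elements) if x == e]
        perm[idx] = rng.permutation(idx)
    b = LigandPose(
        "b",
        [elements[i] for i in perm],
        coords[perm] + rng.normal(0.0, noise, (len(elements), 3)),
    )
    return a, b


@pytest.fixture(scope="session")
def make_pose_pair():
    return random_pose_pair
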