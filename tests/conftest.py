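"""Shared fixtures: simulated study conditions reused across test modules.

Session scope keeps the expensive 15 kb / 60x insect fixture to a single
simulation per run.
"""

from __future__ import annotations

import pytest

from mitoskim.simulate import (
    SimConfig,
    make_bait,
    make_reference_peptides,
    make_reference_rrnas,
    simulate_mitogenome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def insect_cfg() -> SimConfig:
    """The protocol's insect-mode study conditions: 15 kb circular genome,
    60x PE-150 at 1% error, bait at 5% divergence."""
    return SimConfig(rng_seed=7)


@pytest.fixture(scope="session")
def insect_truth(insect_cfg):
    return simulate_mitogenome(insect_cfg)


@pytest.fixture(scope="session")
def insect_reads(insect_truth, insect_cfg):
    return simulate_reads(insect_truth, insect_cfg)


@pytest.fixture(scope="session")
def insect_bait(insect_truth, insect_cfg):
    return make_bait(insect_truth, insect_cfg)


@pytest.fixture(scope="session")
def insect_refs(insect_truth):
    return (
        make_reference_peptides(insect_truth),
        make_reference_rrnas(insect_truth),
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A 6 kb genome at 40x: cheap enough for per-module unit tests."""
    return SimConfig(rng_seed=3, genome_len=6000, coverage=40)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate_mitogenome(small_cfg)


@pytest.fixture(scope="session")
def small_reads(small_truth, small_cfg):
    return simulate_reads(small_truth, small_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Error-free 6 kb fixture for exact-recovery assertions."""
    return SimConfig(rng_seed=5, genome_len=6000, coverage=40, error_rate=0.0)


@pytest.fixture(scope="session")
def clean_truth(clean_cfg):
    return simulate_mitogenome(clean_cfg)


@pytest.fixture(scope="session")
def clean_reads(clean_truth, clean_cfg):
    return simulate_reads(clean_truth, clean_cfg)


def rotation_of(seq: str, reference: str) -> str | None:
    """Return ``reference`` rotated to align with ``seq``'s origin.

    Probes are turned into IUPAC-aware regular expressions so consensus
    sequences rich in ambiguity codes still anchor; None if nothing maps.
    """
    import re

    from mitoskim.annotate import _IUPAC_EXPAND

    doubled = reference + reference
    off = 0
    while off < len(seq) - 60:
        probe = seq[off : off + 60]
        pattern = "".join(
            f"[{_IUPAC_EXPAND[c]}]" if c in _IUPAC_EXPAND else re.escape(c)
            for c in probe
        )
        m = re.search(pattern, doubled)
        if m:
            start = (m.start() - off) % len(reference)
            return (reference + reference)[start : start + len(reference)]
        off += 60
    return None


def iupac_compatible_identity(called: str, truth: str) -> float:
    """Fraction of positions where the true base is within the called
    (possibly ambiguous) base's IUPAC set."""
    from mitoskim._seq import IUPAC_CODES

    sets = {v: k for k, v in IUPAC_CODES.items()}
    n = min(len(called), len(truth))
    if n == 0:
        return 0.0
    match = sum(
        truth[i] in sets.get(called[i], frozenset(called[i])) for i in range(n)
    )
    return match / max(len(called), len(truth))
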