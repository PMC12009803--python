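"""Shared fixtures: tiny deterministic whitelists, layouts, read builders."""

import numpy as np
import pytest

from clonetrace import (
    BarcodeWhitelist,
    ReadLayout,
    SimulationConfig,
    build_library,
    default_layout,
)
from clonetrace.simulate import _clone_template


@pytest.fixture(scope="session")
def small_whitelist() -> BarcodeWhitelist:
    """6 x 8 deterministic random whitelist (48 possible pairs)."""
    cfg = SimulationConfig(seed=20_240_101, n_bc14=6, n_bc30=8)
    return build_library(cfg)


@pytest.fixture(scope="session")
def layout() -> ReadLayout:
    """Default layout: BC14 | TGGT | BC30, 48-nt reads."""
    return default_layout()


def make_read(bc14: str, bc30: str, layout: ReadLayout) -> str:
    """Paste a barcode pair into the layout template (perfect read)."""
    return _clone_template(bc14 + bc30, layout)


@pytest.fixture(scope="session")
def read_builder(layout):
    return lambda b14, b30: make_read(b14, b30, layout)


def naive_clone_counts(seqs, layout, whitelist, clone_key_mode="pair"):
    """Independent brute-force oracle: slice substrings, test membership.

    Deliberately written from the matching rule's definition, not shared
    with the implementation under test.
    """
    counts = {}
    b14_lo = layout.bc14_offset
    b30_lo = layout.bc30_offset
    for s in seqs:
        if len(s) < layout.min_read_length:
            continue
        s = s.upper()
        b14 = s[b14_lo:b14_lo + 14]
        b30 = s[b30_lo:b30_lo + 30]
        spacer_ok = (layout.spacer is None
                     or s[b14_lo + 14:b30_lo] == layout.spacer)
        pair_ok = (whitelist.valid_pairs is None
                   or (b14, b30) in whitelist.valid_pairs)
        if (spacer_ok and b14 in whitelist.bc14_set
                and b30 in whitelist.bc30_set and pair_ok):
            key = b14 + b30 if clone_key_mode == "pair" else b30
            counts[key] = counts.get(key, 0) + 1
    return counts


def random_count_table(rng: np.random.Generator, n_clones: int):
    """Random clone-key -> count mapping (pair-mode keys)."""
    from clonetrace.simulate import _random_kmers

    b14s = _random_kmers(max(2, n_clones // 8 + 1), 14, rng)
    b30s = _random_kmers(n_clones, 30, rng)
    keys = {rng.choice(b14s) + b30s[i] for i in range(n_clones)}
    return {k: int(rng.integers(1, 1000)) for k in sorted(keys)}
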