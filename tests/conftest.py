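"""Shared fixtures and independent test oracles.

The oracles here are deliberately naive re-derivations (plain Python loops,
closed-form statistics) so that agreement with the library is informative.
"""

from __future__ import annotations

import numpy as np
import pytest

from drgfilter.simulate import biphasic_template

FS = 30_000.0


def greedy_match_oracle(sn, dr, w):
    """Brute-force greedy matcher: DR spikes in ascending time, each takes
    the nearest strictly-preceding unclaimed SN spike within the window.

    Returns ({sn_index: (dr_index, latency)}, [orphan dr indices]).
    Ties in latency (impossible for strictly increasing SN times) would go
    to the later SN spike, matching the declared convention.
    """
    claimed = set()
    pairs = {}
    orphans = []
    for j, t in enumerate(dr):
        cands = [(t - s, -i) for i, s in enumerate(sn)
                 if 0.0 < t - s <= w and i not in claimed]
        if cands:
            lat, neg_i = min(cands)
            i = -neg_i
            claimed.add(i)
            pairs[i] = (j, lat)
        else:
            orphans.append(j)
    return pairs, orphans


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


@pytest.fixture
def template_bank():
    """Three clearly distinct biphasic templates at 30 kHz."""
    return [
        biphasic_template(FS, amplitude=1.0, width=1.2e-4, polarity=-1, asym=0.9),
        biphasic_template(FS, amplitude=1.0, width=2.8e-4, polarity=+1, asym=0.8),
        biphasic_template(FS, amplitude=1.0, width=4.5e-4, polarity=-1, asym=0.3),
    ]


def waveform_cloud(templates, n_per, noise_sd, seed):
    """Stack noisy copies of each template; returns (waveforms, true labels)."""
    r = np.random.default_rng(seed)
    length = min(len(t) for t in templates)
    rows, labels = [], []
    for u, t in enumerate(templates):
        rows.append(t[:length] + r.normal(0.0, noise_sd, size=(n_per, length)))
        labels.extend([u] * n_per)
    return np.vstack(rows), np.asarray(labels)
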