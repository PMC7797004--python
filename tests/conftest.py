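import numpy as np
import pandas as pd
import pytest

import rohmap as rm
from rohmap.panel import MISSING


@pytest.fixture(scope="session")
def tiny_panel():
    """Small simulated panel with pedigree structure, clones and missingness."""
    panel, truth = rm.simulate_panel(rm.tiny_config(seed=11))
    return panel, truth


@pytest.fixture(scope="session")
def midsize_panel():
    """Panel with inbred lines and 4 subpopulations, used by ROH/structure tests."""
    cfg = rm.SimConfig(seed=7, n_founders=40, markers_per_chrom=625,
                       selfing_generations=(2, 3, 4, 5), missing_rate=0.1)
    panel, truth = rm.simulate_panel(cfg)
    return panel, truth


def make_panel(dosages, positions=None, chrom="1", sample_ids=None):
    """Hand-built panel from a dosage list-of-lists (rows = samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if positions is None:
        positions = (np.arange(L) + 1) * 10_000
    markers = pd.DataFrame({"chrom": chrom, "pos": positions})
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return rm.GenotypePanel(sample_ids=ids, markers=markers, dosages=dosages)


def roh_string_oracle(panel, min_snps=15, min_length=100_000, max_gap=1_000_000):
    """Independent ROH enumerator: encode each chromosome as a string with
    '|' breaks at hets and large gaps, split, and strip missing ends."""
    out = []
    for s, sid in enumerate(panel.sample_ids):
        for chrom, sub in panel.markers.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            pos = sub["pos"].to_numpy()
            g = panel.dosages[s, idx]
            chars, marker_of = [], []
            for k in range(len(idx)):
                if k > 0 and pos[k] - pos[k - 1] > max_gap:
                    chars.append("|")
                    marker_of.append(None)
                chars.append("|" if g[k] == 1 else ("m" if g[k] == MISSING else "h"))
                marker_of.append(k)
            text = "".join(chars)
            start = 0
            for frag in text.split("|"):
                if frag:
                    lead = len(frag) - len(frag.lstrip("m"))
                    core = frag.strip("m")
                    if core:
                        a = marker_of[start + lead]
                        b = marker_of[start + lead + len(core) - 1]
                        n_snps = b - a + 1
                        length = int(pos[b] - pos[a] + 1)
                        if n_snps >= min_snps and length >= min_length:
                            out.append((sid, str(chrom), int(pos[a]),
                                        int(pos[b]), n_snps))
                start += len(frag) + 1
    return sorted(out)
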