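import numpy as np
import pytest

from sceqtlmr.core_io import AssocStat, LDPanel


def make_stat(variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
              beta=0.1, se=0.05, p=None, eaf=0.3, n=120.0, **kw) -> AssocStat:
    """AssocStat helper with a self-consistent p unless given."""
    if p is None:
        from scipy.stats import norm
        z = abs(beta / se) if se > 0 else 0.0
        p = float(max(2 * norm.sf(z), 1e-300))
    return AssocStat(variant_id=variant_id, chrom=chrom, pos=pos,
                     effect_allele=ea, other_allele=oa, beta=beta, se=se,
                     p=p, eaf=eaf, n=n, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_panel(rng):
    """200-sample panel of 8 variants: pairs (v0,v1) and (v2,v3) in strong
    LD, the rest independent."""
    n = 200
    cols = {}
    base = rng.binomial(2, 0.3, size=n).astype(float)
    cols["v0"] = base
    noise = rng.binomial(1, 0.01, size=n)
    cols["v1"] = np.clip(base + noise - rng.binomial(1, 0.01, size=n), 0, 2)
    base2 = rng.binomial(2, 0.4, size=n).astype(float)
    cols["v2"] = base2
    cols["v3"] = np.clip(base2 + rng.binomial(1, 0.04, size=n)
                         - rng.binomial(1, 0.04, size=n), 0, 2)
    for k in range(4, 8):
        cols[f"v{k}"] = rng.binomial(2, 0.25, size=n).astype(float)
    ids = list(cols)
    return LDPanel(np.column_stack([cols[v] for v in ids]), ids)
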