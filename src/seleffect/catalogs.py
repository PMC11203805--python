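"""Packaged synthetic signature catalog.

Real analyses use a COSMIC-layout CSV supplied by the user; nothing is
fetched from the network. For tests, demos and simulations the package
ships a deterministic five-signature catalog whose signatures have
partially disjoint channel support, which keeps non-negative least-squares
attribution well conditioned and makes mixture-recovery checks meaningful.
"""

from __future__ import annotations

import numpy as np

from .channels import N_CHANNELS
from .io import SignatureCatalog

# Fixed construction seed: the catalog is a package constant, not a sample.
_CATALOG_SEED = 961405

# Channel blocks where each synthetic signature concentrates its mass.
_SUPPORT_BLOCKS = (
    range(0, 16),    # C>A
    range(16, 32),   # C>G
    range(32, 48),   # C>T
    range(48, 80),   # T>A and T>C
    range(80, 96),   # T>G
)

#: fraction of each signature's mass inside its support block
_BLOCK_MASS = 0.85


def synthetic_signature_catalog() -> SignatureCatalog:
    """The packaged five-signature synthetic catalog (deterministic)."""
    rng = np.random.default_rng(_CATALOG_SEED)
    cols = []
    for block in _SUPPORT_BLOCKS:
        block = np.fromiter(block, dtype=int)
        sig = np.full(N_CHANNELS, (1.0 - _BLOCK_MASS) / (N_CHANNELS - len(block)))
        sig[block] = _BLOCK_MASS * rng.dirichlet(np.full(len(block), 2.0))
        cols.append(sig / sig.sum())
    names = tuple(f"SBS_SYN{i + 1}" for i in range(len(cols)))
    return SignatureCatalog(names=names, matrix=np.column_stack(cols))
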