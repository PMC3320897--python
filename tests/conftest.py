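import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radphylo.digest import LocusTruth, RadRead
from radphylo.synth import make_fixture


def make_read(seq: str, taxon: str = "t", read_id: str | None = None,
              site_column: int | None = None, side: str = "upstream") -> RadRead:
    """Convenience constructor for a read with optional truth label."""
    truth = LocusTruth(site_column=site_column, side=side) if site_column is not None else None
    return RadRead(
        read_id=read_id or f"{taxon}:{seq[:6]}:{id(seq) % 9973}",
        taxon=taxon,
        contig="c",
        side=side,
        interval=(0, len(seq)),
        sequence=seq,
        truth=truth,
    )


def random_seqs(rng: np.random.Generator, n: int, length: int, n_loci: int = 0,
                mut: float = 0.1) -> list[str]:
    """Random read set: ``n_loci`` mutated families plus random background."""
    bases = np.array(list("ACGT"))
    seqs = []
    families = [rng.integers(0, 4, length) for _ in range(n_loci)] if n_loci else []
    for i in range(n):
        if families and i % 2 == 0:
            base = families[i % n_loci].copy()
            hit = rng.random(length) < mut
            base[hit] = (base[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
            seqs.append("".join(bases[base]))
        else:
            seqs.append("".join(bases[rng.integers(0, 4, length)]))
    return seqs


@pytest.fixture(scope="session")
def tiny_data():
    """Small 4-taxon simulated data set (motif-protected, no indels)."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def dros12_data():
    """12-taxon simulated data set, motif-protected, no indels."""
    return make_fixture("dros12", seed=11)
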