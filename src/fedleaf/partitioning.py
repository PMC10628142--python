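"""IID partitioning of the training pool across federated clients.

One seeded uniform shuffle of the training indices is dealt contiguously to
the ``C`` clients.  Partition sizes differ by at most one item; when the
pool size is not divisible by ``C`` the lowest-numbered clients take the
remainder — the deterministic near-equal relaxation of exactly equal
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClientPartition:
    """The index subset of the training pool owned by one client."""

    client_id: int
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"client {self.client_id}: duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


def iid_partition(
    n_items: int, n_clients: int, seed: int
) -> list[ClientPartition]:
    """Split ``0..n_items-1`` equally and at random among ``n_clients``.

    Returns disjoint partitions covering every index, sizes within one of
    each other, deterministic per seed.
    """
    if n_clients < 1:
        raise ValueError(f"n_clients must be >= 1, got {n_clients}")
    if n_items < n_clients:
        raise ValueError(
            f"cannot give {n_clients} clients at least one of {n_items} items"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    base, rem = divmod(n_items, n_clients)
    partitions = []
    start = 0
    for k in range(n_clients):
        size = base + (1 if k < rem else 0)
        partitions.append(ClientPartition(k, order[start : start + size]))
        start += size
    return partitions


def partition_table(partitions: list[ClientPartition]) -> pd.DataFrame:
    """Two-column audit table (index, client_id), sorted by index."""
    rows = [
        (int(i), p.client_id) for p in partitions for i in p.indices
    ]
    df = pd.DataFrame(rows, columns=["index", "client_id"])
    return df.sort_values("index", ignore_index=True)
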