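"""Deterministic seed derivation.

All stochastic stages (partitioning, per-round per-client batch shuffles,
model init) draw their seeds from one experiment-level base seed through a
stable hash, so runs are bit-reproducible while rounds and clients remain
decorrelated.
"""

import hashlib

_MOD = 2**31  # keep derived seeds small non-negative ints


def derive_seed(base_seed: int, *parts) -> int:
    """Hash ``(base_seed, *parts)`` into a seed in [0, 2**31).

    Stable across processes and platforms (unlike ``hash()``).
    """
    payload = repr((int(base_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "little") % _MOD


def client_round_seed(base_seed: int, round_index: int, client_id: int) -> int:
    """Seed for one client's local training in one communication round."""
    return derive_seed(base_seed, "client-round", round_index, client_id)


def train_partition_seed(base_seed: int) -> int:
    return derive_seed(base_seed, "train-partition")


def test_partition_seed(base_seed: int) -> int:
    return derive_seed(base_seed, "test-partition")


def model_init_seed(base_seed: int, spec_init_seed: int = 0) -> int:
    """Effective model-init seed: mixes the experiment base seed with the
    model spec's own init_seed so different experiments start from
    different initial weights."""
    return derive_seed(base_seed, "model-init", spec_init_seed)
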