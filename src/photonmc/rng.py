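"""Reproducible, non-overlapping uniform substreams for parallel workers.

Monte Carlo parallelization here is random-stream parallelization: each
worker owns a private substream and the host merges the tallies.  The
substreams are counter-based (Philox4x32-10): worker ``i`` of a run with
master seed ``s`` draws from the keyed sequence ``key = (s, i)``, so streams
from different workers are disjoint by construction — no jump-ahead
bookkeeping and no inter-worker communication beyond the seed.

Identical ``(master_seed, n_workers, worker_index)`` always reproduces the
identical substream, which makes whole simulations bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from ._kernels import _philox_block, fill_uniform

__all__ = ["SubStream", "make_substreams"]

_GOLDEN = 0x9E3779B9
_MASK32 = 0xFFFFFFFF


def _stream_key(master_seed: int, worker_index: int) -> tuple[int, int]:
    k0 = master_seed & _MASK32
    k1 = ((master_seed >> 32) & _MASK32) ^ ((worker_index * _GOLDEN) & _MASK32)
    return k0, k1


class SubStream:
    """One worker's uniform-[0,1) stream (stateful, deterministic).

    Parameters
    ----------
    master_seed
        Nonnegative run seed shared by all workers.
    worker_index
        0-based worker id; distinct ids give disjoint streams.
    """

    def __init__(self, master_seed: int, worker_index: int = 0):
        if master_seed < 0:
            raise ValueError("master_seed must be nonnegative")
        if worker_index < 0:
            raise ValueError("worker_index must be nonnegative")
        self.master_seed = int(master_seed)
        self.worker_index = int(worker_index)
        self._k0, self._k1 = _stream_key(self.master_seed, self.worker_index)
        self._block = 0        # next Philox counter block
        self._spare: float | None = None

    @property
    def key(self) -> tuple[int, int]:
        """The (k0, k1) Philox key identifying this substream."""
        return self._k0, self._k1

    def uniform(self) -> float:
        """Next uniform draw xi in [0, 1) (stateful advance)."""
        if self._spare is not None:
            u, self._spare = self._spare, None
            return u
        u0, u1 = _philox_block(np.uint64(self._block),
                               np.uint64(self._k0), np.uint64(self._k1))
        self._block += 1
        self._spare = float(u1)
        return float(u0)

    def uniforms(self, n: int) -> np.ndarray:
        """Vector of the next ``n`` uniform draws."""
        if n < 0:
            raise ValueError("n must be nonnegative")
        out = np.empty(n, dtype=np.float64)
        i = 0
        if self._spare is not None and n > 0:
            out[0] = self._spare
            self._spare = None
            i = 1
        if n - i > 0:
            self._block = int(fill_uniform(
                out[i:], np.uint64(self._k0), np.uint64(self._k1),
                self._block))
            # fill_uniform consumes whole blocks; drop any half-block spare
            if (n - i) % 2 == 1:
                pass  # the odd half of the last block is discarded
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SubStream(master_seed={self.master_seed}, "
                f"worker_index={self.worker_index}, block={self._block})")


def make_substreams(master_seed: int, n_workers: int) -> list[SubStream]:
    """Create ``n_workers`` pairwise non-overlapping uniform substreams.

    Each substream is a distinct Philox key, so the sequences are disjoint by
    construction for any number of draws.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    return [SubStream(master_seed, i) for i in range(n_workers)]
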