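"""Simulated secure aggregation via additive secret sharing.

Values are encoded in fixed point (default 16 fractional bits) on the ring
Z_{2^64} with two's-complement sign convention, split into additive shares
across computational parties, and recombined by modular summation. Two
protocols are built on top: a secure weighted sum backing federated
averaging, and a secure argmax backing dominant-batch detection, which
reveals only pairwise comparison outcomes — never the counts themselves.

Everything runs in-process; "parties" are instrumented containers whose
message transcripts can be asserted in privacy tests. This is an
honest-but-curious simulation, not a hardened deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedPoint",
    "AdditiveShares",
    "Transcript",
    "share",
    "reconstruct",
    "secure_weighted_sum",
    "secure_argmax",
]

_RING_BITS = 64


@dataclass(frozen=True)
class FixedPoint:
    """Fixed-point encoding: value ~ round(x * 2**fractional_bits) mod 2**64."""

    fractional_bits: int = 16

    @property
    def scale(self) -> float:
        return float(1 << self.fractional_bits)

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        scaled = np.round(x * self.scale)
        limit = 2.0 ** (_RING_BITS - 1)
        if np.any(np.abs(scaled) >= limit):
            raise OverflowError("value exceeds the fixed-point representable range")
        return scaled.astype(np.int64).astype(np.uint64)

    def decode(self, r: np.ndarray) -> np.ndarray:
        return r.astype(np.uint64).astype(np.int64).astype(np.float64) / self.scale


@dataclass
class AdditiveShares:
    """One uint64 share array per party; modular sum decodes to the value."""

    party_shares: list
    encoding: FixedPoint

    @property
    def n_parties(self) -> int:
        return len(self.party_shares)

    def __add__(self, other: "AdditiveShares") -> "AdditiveShares":
        if self.encoding != other.encoding or self.n_parties != other.n_parties:
            raise ValueError("share encodings or party counts differ")
        with np.errstate(over="ignore"):
            summed = [a + b for a, b in zip(self.party_shares, other.party_shares)]
        return AdditiveShares(summed, self.encoding)


@dataclass
class Transcript:
    """Log of values each party/coordinator observes during a protocol."""

    messages: list = field(default_factory=list)

    def record(self, receiver: str, kind: str, payload) -> None:
        self.messages.append({"receiver": receiver, "kind": kind, "payload": payload})

    def seen_by(self, receiver: str) -> list:
        return [m for m in self.messages if m["receiver"] == receiver]


def share(
    tensor: np.ndarray,
    n_parties: int,
    rng: np.random.Generator,
    encoding: FixedPoint | None = None,
) -> AdditiveShares:
    """Split a tensor into ``n_parties`` additive shares.

    The first ``n_parties - 1`` shares are uniform on the ring; the last is
    the encoded value minus their modular sum, so any proper subset of
    shares is statistically independent of the value.
    """
    if n_parties < 2:
        raise ValueError("need at least 2 parties")
    enc = encoding or FixedPoint()
    encoded = enc.encode(tensor)
    shares = [
        rng.integers(0, 2**_RING_BITS, size=encoded.shape, dtype=np.uint64)
        for _ in range(n_parties - 1)
    ]
    with np.errstate(over="ignore"):
        partial = np.zeros_like(encoded)
        for s in shares:
            partial = partial + s
        shares.append(encoded - partial)
    return AdditiveShares(shares, enc)


def reconstruct(shares: AdditiveShares) -> np.ndarray:
    """Modular sum of shares, then fixed-point decode."""
    with np.errstate(over="ignore"):
        total = np.zeros_like(shares.party_shares[0])
        for s in shares.party_shares:
            total = total + s
    return shares.encoding.decode(total)


def secure_weighted_sum(
    client_tensors: list,
    client_weights: list,
    n_parties: int = 3,
    rng: np.random.Generator | None = None,
    transcript: Transcript | None = None,
) -> np.ndarray:
    """Weighted average of client tensors without revealing any single one.

    Each client shares ``weight * tensor`` and ``weight``; parties add
    shares element-wise; the coordinator reconstructs only the two sums and
    divides. Matches plaintext sample-size-weighted averaging to within the
    fixed-point resolution.
    """
    if len(client_tensors) != len(client_weights):
        raise ValueError("one weight per client required")
    if any(w <= 0 for w in client_weights):
        raise ValueError("weights must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    enc = FixedPoint()
    num_sum = None
    w_sum = None
    for x, w in zip(client_tensors, client_weights):
        s_num = share(np.asarray(x, dtype=np.float64) * float(w), n_parties, rng, enc)
        s_w = share(np.asarray(float(w)), n_parties, rng, enc)
        if transcript is not None:
            for p in range(n_parties):
                transcript.record(f"party_{p}", "share", s_num.party_shares[p])
        num_sum = s_num if num_sum is None else num_sum + s_num
        w_sum = s_w if w_sum is None else w_sum + s_w
    numerator = reconstruct(num_sum)
    denominator = float(reconstruct(w_sum))
    if transcript is not None:
        transcript.record("coordinator", "share_sum", numerator)
        transcript.record("coordinator", "weight_sum", denominator)
    return numerator / denominator


def secure_argmax(
    per_client_counts: dict,
    n_parties: int = 3,
    rng: np.random.Generator | None = None,
    transcript: Transcript | None = None,
):
    """Identity of the client with the largest count, via shared comparisons.

    Counts are secret-shared; parties evaluate the sign of pairwise
    differences of shares and reveal only comparison outcomes, from which
    the winner follows. Ties resolve to the smallest client id. The counts
    themselves are never reconstructed.
    """
    if not per_client_counts:
        raise ValueError("no clients")
    if all(c == 0 for c in per_client_counts.values()):
        raise ValueError("all counts are zero; no dominant client exists")
    rng = rng if rng is not None else np.random.default_rng()
    enc = FixedPoint(fractional_bits=0)
    shared_counts = {
        c: share(np.asarray(float(n)), n_parties, rng, enc) for c, n in per_client_counts.items()
    }
    clients = sorted(per_client_counts)
    best = clients[0]
    for challenger in clients[1:]:
        # parties jointly open only the sign of (count_challenger - count_best)
        with np.errstate(over="ignore"):
            diff_shares = AdditiveShares(
                [a - b for a, b in zip(
                    shared_counts[challenger].party_shares, shared_counts[best].party_shares
                )],
                enc,
            )
        challenger_wins = bool(reconstruct(diff_shares) > 0)
        if transcript is not None:
            transcript.record(
                "coordinator", "comparison_bit",
                {"pair": (challenger, best), "challenger_wins": challenger_wins},
            )
        if challenger_wins:
            best = challenger
    if transcript is not None:
        transcript.record("coordinator", "argmax_winner", best)
    return best
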