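"""Client/aggregator protocol simulation and the two privacy primitives.

Federated training here follows the canonical loop: every client is
initialized with the same model architecture, trains locally, communicates
only parameters or statistics to the aggregator, which combines them into the
shared model; the loop repeats for a configured number of rounds.  Raw rows
never cross the client boundary — the protocol runner only ever forwards what
the local-training callback returns, and a JSON-lines trace of every payload
can be kept for auditing.

Privacy primitives
------------------
* **SMPC sums** via additive secret sharing over the 2⁶⁴ integer ring with a
  fixed-point encoding (scale 2¹⁶ by default).  Each client splits its tensor
  into uniformly random shares that sum to the encoded value modulo 2⁶⁴; the
  aggregator only ever adds share tensors, so the sum over clients is exact
  at the fixed-point precision while any proper subset of shares carries no
  information about a client's plaintext.
* **(ε, δ)-differential privacy** via the Gaussian mechanism: noise with
  σ = sensitivity · √(2 ln(1.25/δ)) / ε, the standard calibration valid for
  ε ≤ 1 (the regime used here, ε = 1, δ = 1e−5).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "FedConfig",
    "SecretShares",
    "DPConfig",
    "smpc_share",
    "smpc_aggregate",
    "dp_perturb",
    "gaussian_sigma",
    "run_protocol",
    "ProtocolTrace",
]

DEFAULT_FIXED_POINT_SCALE = 1 << 16
_RING_BITS = 64
# headroom so encoded magnitudes stay clear of the ring boundary
_MAX_ENCODED = 1 << 62


@dataclass(frozen=True)
class FedConfig:
    """Protocol plan: client count, rounds, local steps, aggregation rule."""

    n_clients: int
    rounds: int = 1
    local_steps: int = 1
    aggregation: str = "weighted-average"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ValueError("need at least one client")
        if self.rounds < 1 or self.local_steps < 1:
            raise ValueError("rounds and local_steps must be >= 1")
        if self.aggregation not in ("weighted-average", "pooling"):
            raise ValueError(f"unknown aggregation rule {self.aggregation!r}")


@dataclass
class SecretShares:
    """Additive shares of one fixed-point-encoded tensor."""

    shares: list[np.ndarray]
    scale: int = DEFAULT_FIXED_POINT_SCALE

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.shares}
        if len(shapes) != 1:
            raise ValueError("all shares must have identical shape")
        for s in self.shares:
            if s.dtype != np.uint64:
                raise ValueError("shares must live in the uint64 ring")

    @property
    def n_parties(self) -> int:
        return len(self.shares)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.shares[0].shape


@dataclass(frozen=True)
class DPConfig:
    """(ε, δ) budget and mechanism parameters for one released quantity."""

    epsilon: float = 1.0
    delta: float = 1e-5
    mechanism: str = "gaussian"
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.mechanism not in ("gaussian", "bypass"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")

    @property
    def bypassed(self) -> bool:
        """ε→∞ limit: release values untouched (for ablation baselines)."""
        return self.mechanism == "bypass" or math.isinf(self.epsilon)


def _encode(value: np.ndarray, scale: int) -> np.ndarray:
    value = np.asarray(value, dtype=float)
    if not np.isfinite(value).all():
        raise ValueError("cannot share non-finite values")
    encoded = np.rint(value * scale)
    if np.abs(encoded).max(initial=0.0) >= _MAX_ENCODED:
        raise ValueError("value magnitude exceeds the fixed-point range")
    return encoded.astype(np.int64).view(np.uint64)


def _decode(ring_value: np.ndarray, scale: int) -> np.ndarray:
    return ring_value.view(np.int64).astype(float) / scale


def smpc_share(
    value: np.ndarray,
    n_parties: int,
    seed: int,
    scale: int = DEFAULT_FIXED_POINT_SCALE,
) -> SecretShares:
    """Split a tensor into ``n_parties`` additive shares over the 2⁶⁴ ring.

    The first ``n_parties − 1`` shares are uniform over the ring; the last is
    the encoded value minus their ring sum, so the shares decode to the exact
    fixed-point value while each individual share is marginally uniform.
    """
    if n_parties < 1:
        raise ValueError("need at least one party")
    encoded = _encode(np.asarray(value, dtype=float), scale)
    rng = np.random.default_rng(seed)
    shares = [rng.integers(0, 2**_RING_BITS, size=encoded.shape, dtype=np.uint64) for _ in range(n_parties - 1)]
    with np.errstate(over="ignore"):
        last = encoded.copy()
        for s in shares:
            last = last - s  # uint64 arithmetic wraps mod 2^64
    shares.append(last)
    return SecretShares(shares=shares, scale=scale)


def smpc_aggregate(all_shares: Sequence[SecretShares]) -> np.ndarray:
    """Exact plaintext **sum over clients** from their secret shares.

    The aggregator adds share tensors in the ring and decodes only the final
    total, so no individual client's plaintext is ever materialized.
    """
    if not all_shares:
        raise ValueError("nothing to aggregate")
    shape = all_shares[0].shape
    scale = all_shares[0].scale
    for s in all_shares:
        if s.shape != shape or s.scale != scale:
            raise ValueError("mismatched share shapes or encodings")
    total = np.zeros(shape, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for client_shares in all_shares:
            for share in client_shares.shares:
                total = total + share
    return _decode(total, scale)


def gaussian_sigma(cfg: DPConfig) -> float:
    """Noise scale of the Gaussian mechanism for the configured budget."""
    if cfg.delta <= 0:
        raise ValueError("the Gaussian mechanism requires delta > 0")
    return cfg.sensitivity * math.sqrt(2.0 * math.log(1.25 / cfg.delta)) / cfg.epsilon


def dp_perturb(values: np.ndarray, cfg: DPConfig, seed: int) -> np.ndarray:
    """Add Gaussian-mechanism noise to a (pre-clipped) tensor.

    Callers are responsible for clipping ``values`` so that one individual's
    record changes them by at most ``cfg.sensitivity``.  With the bypass
    mechanism (the ε→∞ limit) the input is returned bit-identical.
    """
    values = np.asarray(values, dtype=float)
    if cfg.bypassed:
        return values
    rng = np.random.default_rng(seed)
    return values + rng.normal(0.0, gaussian_sigma(cfg), size=values.shape)


class ProtocolTrace:
    """Audit log of everything that crossed the client/aggregator boundary."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def log(self, round_idx: int, client: str, payload: Any) -> None:
        self.records.append(
            {
                "round": round_idx,
                "client": client,
                "payload_kind": type(payload).__name__,
                "payload_shape": _payload_shape(payload),
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(json.dumps(r) for r in self.records) + "\n")


def _payload_shape(payload: Any) -> list:
    if hasattr(payload, "shape"):
        return list(payload.shape)
    if isinstance(payload, (tuple, list)):
        return [_payload_shape(p) for p in payload]
    return []


def run_protocol(
    clients: Sequence[Any],
    plan: FedConfig,
    train_fn: Callable[[Any, Any, int], Any],
    aggregate_fn: Callable[[list[Any], list[str]], Any],
    init_model: Any = None,
    trace: ProtocolTrace | None = None,
) -> Any:
    """Run the local-training → communication → aggregation loop.

    ``train_fn(client, global_model, round_idx)`` runs on each client and may
    return only model parameters or statistics — that return value is the only
    thing handed to ``aggregate_fn(payloads, client_ids)``, which produces the
    next shared model.  Clients whose state reports zero rows (``n == 0`` or
    empty) are skipped with a warning; if every client is empty the protocol
    aborts.
    """
    if len(clients) == 0:
        raise ValueError("no clients")

    def _client_rows(c: Any) -> int:
        if hasattr(c, "n"):
            return int(c.n)
        try:
            return len(c)
        except TypeError:
            return 1

    active = [(str(getattr(c, "site_id", i)), c) for i, c in enumerate(clients)]
    skipped = [cid for cid, c in active if _client_rows(c) == 0]
    for cid in skipped:
        warnings.warn(f"client {cid} has no training rows and is skipped", stacklevel=2)
    active = [(cid, c) for cid, c in active if _client_rows(c) > 0]
    if not active:
        raise ValueError("all clients are empty")

    global_model = init_model
    for round_idx in range(plan.rounds):
        payloads = []
        ids = []
        for cid, client in active:
            payload = train_fn(client, global_model, round_idx)
            if trace is not None:
                trace.log(round_idx, cid, payload)
            payloads.append(payload)
            ids.append(cid)
        global_model = aggregate_fn(payloads, ids)
    return global_model
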