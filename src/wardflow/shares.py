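"""Two-party additive secret sharing over a prime field.

Implements the share-compute-reveal substrate used by the secure pipeline:
integers in a symmetric range [-M, M] are embedded into F_p (p > 2M) and
split into two uniformly random additive shares, one held by the hospital
and one by the labour union.  Linear operations are local; multiplication
consumes one Beaver triple; comparisons use dealer-supplied bit-decomposed
random masks and reveal only statistically masked openings.

The trust model is a semi-honest two-party protocol with a trusted dealer
for preprocessing.  This deliberately downgrades the malicious security a
production SPDZ deployment would provide: the functional semantics of every
gate (what is computed, what is revealed) are preserved, the MAC-checked
execution is not.  Do not use this module to protect real data.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field as dataclass_field

import sympy

from .errors import (
    ConfigurationError,
    PreprocessingExhaustedError,
    RangeError,
)

__all__ = [
    "FieldSpec",
    "SharedValue",
    "BeaverTriple",
    "Dealer",
    "DealerTape",
    "TwoPartyEngine",
    "FIELD_PRESETS",
    "field_for_budget",
]


@dataclass(frozen=True)
class FieldSpec:
    """Prime-field parameters for the signed-integer embedding.

    Parameters
    ----------
    p:
        Field modulus; must be prime.
    stat_sec:
        Statistical security parameter kappa (bits): the advantage an
        adversary gains from a masked comparison opening is <= 2**-kappa.
    comparison_bitlen:
        Default bound l on comparison inputs: secure comparisons accept
        secrets in [-2**(l-1), 2**(l-1)).
    """

    p: int
    stat_sec: int = 40
    comparison_bitlen: int = 64

    def __post_init__(self) -> None:
        if not sympy.isprime(self.p):
            raise ConfigurationError(f"field modulus {self.p} is not prime")
        if self.stat_sec < 1 or self.comparison_bitlen < 1:
            raise ConfigurationError("stat_sec and comparison_bitlen must be >= 1")
        if self.comparison_bitlen + self.stat_sec + 1 > self.p.bit_length():
            raise ConfigurationError(
                f"no comparison headroom: l={self.comparison_bitlen} + "
                f"kappa={self.stat_sec} + 1 exceeds bitlength({self.p.bit_length()})"
            )

    @property
    def signed_bound(self) -> int:
        """Largest magnitude M of an embeddable signed integer (2M < p)."""
        return (self.p - 1) // 2

    def max_comparison_bitlen(self) -> int:
        """Largest l for which the masked comparison opening fits below p."""
        l = 1
        while 2 ** (l + 2) + 2 ** (l + 2 + self.stat_sec) < self.p:
            l += 1
        return l

    def signed(self, residue: int) -> int:
        """Map a field residue to its representative in [-(p-1)/2, (p-1)/2]."""
        residue %= self.p
        return residue if residue <= self.signed_bound else residue - self.p


#: Presets: the 64-bit field matching the reference deployment's parameters,
#: the default 127-bit Mersenne field, and a wide 255-bit field for circuits
#: whose worst-case bit growth exceeds the 127-bit headroom.
FIELD_PRESETS: dict[str, FieldSpec] = {
    "p64": FieldSpec(p=2**64 - 59, stat_sec=40, comparison_bitlen=21),
    "p127": FieldSpec(p=2**127 - 1, stat_sec=40, comparison_bitlen=84),
    "p255": FieldSpec(p=2**255 - 19, stat_sec=40, comparison_bitlen=212),
}

DEFAULT_FIELD = FIELD_PRESETS["p127"]


def field_for_budget(required_bitlen: int, stat_sec: int = 40) -> FieldSpec:
    """Smallest preset whose comparison headroom covers ``required_bitlen``."""
    for name in ("p64", "p127", "p255"):
        spec = FIELD_PRESETS[name]
        if spec.stat_sec == stat_sec and required_bitlen <= spec.comparison_bitlen:
            return spec
    raise ConfigurationError(
        f"no field preset offers {required_bitlen} comparison bits; "
        "reduce the iteration count or problem size"
    )


@dataclass(frozen=True, slots=True)
class SharedValue:
    """Additive two-party share: secret = (share_0 + share_1) mod p.

    share_0 is held by the hospital, share_1 by the labour union.  Each
    share alone is uniform and independent of the secret.
    """

    share_0: int
    share_1: int


@dataclass(frozen=True, slots=True)
class BeaverTriple:
    """Preprocessed shared (a, b, c) with c = a*b mod p, a and b uniform."""

    a: SharedValue
    b: SharedValue
    c: SharedValue


class Dealer:
    """Trusted dealer producing correlated randomness on demand.

    Generation is deterministic given ``seed``; consumption counters expose
    exactly how much preprocessing a circuit used.  Optional capacities model
    a finite preprocessing tape: exceeding one raises
    :class:`PreprocessingExhaustedError`.
    """

    def __init__(
        self,
        field: FieldSpec,
        seed: int = 0,
        *,
        triple_capacity: int | None = None,
        bit_capacity: int | None = None,
        mask_capacity: int | None = None,
    ) -> None:
        self.field = field
        self._rng = random.Random(seed)
        self.triple_capacity = triple_capacity
        self.bit_capacity = bit_capacity
        self.mask_capacity = mask_capacity
        self.triples_used = 0
        self.bits_used = 0
        self.bounded_masks_used = 0
        self.nonzero_masks_used = 0

    # -- internal helpers -------------------------------------------------
    def _share(self, x: int) -> SharedValue:
        s0 = self._rng.randrange(self.field.p)
        return SharedValue(s0, (x - s0) % self.field.p)

    def _check(self, used: int, capacity: int | None, what: str) -> None:
        if capacity is not None and used >= capacity:
            raise PreprocessingExhaustedError(f"dealer tape out of {what}")

    # -- tape elements ----------------------------------------------------
    def triple(self) -> BeaverTriple:
        self._check(self.triples_used, self.triple_capacity, "Beaver triples")
        self.triples_used += 1
        a = self._rng.randrange(self.field.p)
        b = self._rng.randrange(self.field.p)
        return BeaverTriple(self._share(a), self._share(b), self._share(a * b % self.field.p))

    def random_bit(self) -> SharedValue:
        self._check(self.bits_used, self.bit_capacity, "shared random bits")
        self.bits_used += 1
        return self._share(self._rng.randrange(2))

    def random_bounded(self, bound: int) -> SharedValue:
        """Shares of a uniform integer in [0, bound) (comparison high mask)."""
        self._check(self.bounded_masks_used, self.mask_capacity, "bounded masks")
        self.bounded_masks_used += 1
        return self._share(self._rng.randrange(bound))

    def random_nonzero(self) -> SharedValue:
        """Shares of a uniform nonzero field element (zero-test mask)."""
        self.nonzero_masks_used += 1
        return self._share(self._rng.randrange(1, self.field.p))

    def counters(self) -> dict[str, int]:
        return {
            "triples": self.triples_used,
            "random_bits": self.bits_used,
            "bounded_masks": self.bounded_masks_used,
            "nonzero_masks": self.nonzero_masks_used,
        }


class DealerTape:
    """A serialized, finite dealer tape: replayable preprocessing.

    Produced by :meth:`record_from`; consumed by passing it as the dealer of
    a :class:`TwoPartyEngine`.  Every element is used at most once; running
    past the end raises :class:`PreprocessingExhaustedError`.
    """

    def __init__(self, field: FieldSpec, elements: list[tuple[str, list[int]]]):
        self.field = field
        self._elements = elements
        self._pos = 0
        self.triples_used = 0
        self.bits_used = 0
        self.bounded_masks_used = 0
        self.nonzero_masks_used = 0

    @classmethod
    def record_from(
        cls,
        dealer: Dealer,
        *,
        triples: int = 0,
        bits: int = 0,
        bounded: int = 0,
        bound: int = 2,
        nonzero: int = 0,
    ) -> "DealerTape":
        """Pre-generate a tape from an on-demand dealer (order: as consumed)."""
        elements: list[tuple[str, list[int]]] = []
        for _ in range(triples):
            t = dealer.triple()
            elements.append(
                ("triple", [t.a.share_0, t.a.share_1, t.b.share_0, t.b.share_1,
                            t.c.share_0, t.c.share_1])
            )
        for _ in range(bits):
            b = dealer.random_bit()
            elements.append(("bit", [b.share_0, b.share_1]))
        for _ in range(bounded):
            r = dealer.random_bounded(bound)
            elements.append(("bounded", [r.share_0, r.share_1]))
        for _ in range(nonzero):
            r = dealer.random_nonzero()
            elements.append(("nonzero", [r.share_0, r.share_1]))
        return cls(dealer.field, elements)

    def _next(self, kind: str) -> list[int]:
        # Tape elements are typed but consumed strictly in order within type.
        for i in range(self._pos, len(self._elements)):
            if self._elements[i][0] == kind:
                element = self._elements.pop(i)
                return element[1]
        raise PreprocessingExhaustedError(f"dealer tape out of {kind} elements")

    def triple(self) -> BeaverTriple:
        v = self._next("triple")
        self.triples_used += 1
        return BeaverTriple(
            SharedValue(v[0], v[1]), SharedValue(v[2], v[3]), SharedValue(v[4], v[5])
        )

    def random_bit(self) -> SharedValue:
        v = self._next("bit")
        self.bits_used += 1
        return SharedValue(v[0], v[1])

    def random_bounded(self, bound: int) -> SharedValue:
        v = self._next("bounded")
        self.bounded_masks_used += 1
        return SharedValue(v[0], v[1])

    def random_nonzero(self) -> SharedValue:
        v = self._next("nonzero")
        self.nonzero_masks_used += 1
        return SharedValue(v[0], v[1])

    def counters(self) -> dict[str, int]:
        return {
            "triples": self.triples_used,
            "random_bits": self.bits_used,
            "bounded_masks": self.bounded_masks_used,
            "nonzero_masks": self.nonzero_masks_used,
        }

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"p": self.field.p, "stat_sec": self.field.stat_sec,
                       "comparison_bitlen": self.field.comparison_bitlen,
                       "elements": self._elements}, fh)

    @classmethod
    def load(cls, path: str) -> "DealerTape":
        with open(path) as fh:
            data = json.load(fh)
        spec = FieldSpec(p=data["p"], stat_sec=data["stat_sec"],
                         comparison_bitlen=data["comparison_bitlen"])
        return cls(spec, [(k, v) for k, v in data["elements"]])


class TwoPartyEngine:
    """Simulated two-party execution: both party states plus the channel.

    All gates are expressed over :class:`SharedValue` pairs; every value that
    would cross the wire in a real deployment goes through :meth:`_open`,
    which records it on the transcript.  The transcript therefore contains
    everything either party could observe beyond its own shares, making
    leakage claims directly testable.
    """

    def __init__(
        self,
        field: FieldSpec,
        dealer: Dealer | DealerTape | None = None,
        *,
        share_seed: int = 0,
        record_gates: bool = False,
        record_openings: bool = False,
    ) -> None:
        self.field = field
        self.dealer = dealer if dealer is not None else Dealer(field, seed=share_seed + 1)
        self._rng = random.Random(share_seed)
        self.gate_counts: Counter[str] = Counter()
        self.gate_trace: list[str] | None = [] if record_gates else None
        self.openings: list[int] | None = [] if record_openings else None
        self.reveals: list[tuple[str, int]] = []

    # -- bookkeeping ------------------------------------------------------
    def _gate(self, name: str) -> None:
        self.gate_counts[name] += 1
        if self.gate_trace is not None:
            self.gate_trace.append(name)

    def _open(self, v: SharedValue) -> int:
        """Joint opening of a masked value (the only on-wire data)."""
        val = (v.share_0 + v.share_1) % self.field.p
        if self.openings is not None:
            self.openings.append(val)
        return val

    # -- sharing and revealing --------------------------------------------
    def share(self, x: int) -> SharedValue:
        """Secret-share an integer in the symmetric range [-M, M]."""
        if abs(x) > self.field.signed_bound:
            raise RangeError(f"|{x}| exceeds the field's signed bound")
        s0 = self._rng.randrange(self.field.p)
        return SharedValue(s0, (x - s0) % self.field.p)

    def share_public(self, c: int) -> SharedValue:
        """Trivial sharing of a public constant (share_1 = 0)."""
        return SharedValue(c % self.field.p, 0)

    def reveal(self, v: SharedValue, label: str = "output") -> int:
        """Jointly reconstruct an output, mapped to the signed range."""
        self._gate("reveal")
        val = self.field.signed((v.share_0 + v.share_1) % self.field.p)
        self.reveals.append((label, val))
        return val

    # -- linear gates (local, no interaction) ------------------------------
    def add(self, u: SharedValue, v: SharedValue) -> SharedValue:
        p = self.field.p
        return SharedValue((u.share_0 + v.share_0) % p, (u.share_1 + v.share_1) % p)

    def sub(self, u: SharedValue, v: SharedValue) -> SharedValue:
        p = self.field.p
        return SharedValue((u.share_0 - v.share_0) % p, (u.share_1 - v.share_1) % p)

    def neg(self, u: SharedValue) -> SharedValue:
        p = self.field.p
        return SharedValue(-u.share_0 % p, -u.share_1 % p)

    def add_const(self, u: SharedValue, c: int) -> SharedValue:
        # Convention: party 0 adjusts its share by the public constant.
        return SharedValue((u.share_0 + c) % self.field.p, u.share_1)

    def mul_const(self, u: SharedValue, c: int) -> SharedValue:
        p = self.field.p
        return SharedValue(u.share_0 * c % p, u.share_1 * c % p)

    # -- interactive gates -------------------------------------------------
    def mul(self, u: SharedValue, v: SharedValue) -> SharedValue:
        """Beaver multiplication: one triple, two masked openings."""
        self._gate("mul")
        t = self.dealer.triple()
        d = self._open(self.sub(u, t.a))
        e = self._open(self.sub(v, t.b))
        res = self.add(t.c, self.mul_const(t.b, d))
        res = self.add(res, self.mul_const(t.a, e))
        return self.add_const(res, d * e % self.field.p)

    def lt(self, u: SharedValue, v: SharedValue, bitlen: int | None = None) -> SharedValue:
        """Shared bit (u < v) for secrets in [-2**(l-1), 2**(l-1)).

        Statistically masked comparison: z = u - v lies in (-2**l, 2**l);
        z + 2**l is opened under a (l+1+kappa)-bit random mask whose low l
        bits the dealer supplied in shared bit-decomposed form, and the sign
        bit of z is recovered from a public/shared bitwise comparison.
        """
        self._gate("lt")
        l = self.field.comparison_bitlen if bitlen is None else bitlen
        kappa = self.field.stat_sec
        # Opening bound: (z + 2**l) + r < 2**(l+1) + 2**(l+1+kappa) must stay below p.
        if 2 ** (l + 1) + 2 ** (l + 1 + kappa) >= self.field.p:
            raise ConfigurationError(
                f"comparison bitlen {l} with kappa={kappa} exceeds field headroom"
            )
        m = l  # number of masked low bits = bitlength of |z| range
        p = self.field.p
        z = self.sub(u, v)
        a_shift = self.add_const(z, 2**m)  # in [0, 2**(m+1))

        bits = [self.dealer.random_bit() for _ in range(m)]
        r_prime = self.share_public(0)
        for i, b in enumerate(bits):
            r_prime = self.add(r_prime, self.mul_const(b, 2**i))
        r_high = self.dealer.random_bounded(2 ** (kappa + 1))
        mask = self.add(self.mul_const(r_high, 2**m), r_prime)

        c = self._open(self.add(a_shift, mask))  # integer < p by the bound above
        c_low = c % (2**m)

        # BitLT(c_low, r'): shared bit u_bit = 1 iff c_low < r'.
        c_bits = [(c_low >> i) & 1 for i in range(m)]
        diff = []  # d_i = c_i XOR b_i, linear because c_i is public
        for i in range(m):
            if c_bits[i]:
                diff.append(self.add_const(self.neg(bits[i]), 1))
            else:
                diff.append(bits[i])
        # Suffix OR from the most significant bit; g_i marks the highest
        # differing bit; u_bit = sum g_i * b_i.
        f = diff[m - 1]
        g = [None] * m
        g[m - 1] = diff[m - 1]
        for i in range(m - 2, -1, -1):
            f_new = self.sub(self.add(f, diff[i]), self.mul(f, diff[i]))
            g[i] = self.sub(f_new, f)
            f = f_new
        u_bit = self.share_public(0)
        for i in range(m):
            u_bit = self.add(u_bit, self.mul(g[i], bits[i]))

        # a_shift mod 2**m  =  c_low - r' + 2**m * u_bit
        mod_low = self.add_const(
            self.add(self.neg(r_prime), self.mul_const(u_bit, 2**m)), c_low
        )
        inv_2m = pow(2**m, -1, p)
        msb = self.mul_const(self.sub(a_shift, mod_low), inv_2m)
        # z < 0  <=>  a_shift < 2**m  <=>  msb == 0
        return self.add_const(self.neg(msb), 1)

    def ge(self, u: SharedValue, v: SharedValue, bitlen: int | None = None) -> SharedValue:
        """Shared bit (u >= v): the complement of lt."""
        self._gate("ge")
        return self.add_const(self.neg(self.lt(u, v, bitlen)), 1)

    def eq(self, u: SharedValue, v: SharedValue, bitlen: int | None = None) -> SharedValue:
        """Shared bit (u == v), composed as (u >= v) * (v >= u)."""
        self._gate("eq")
        not_lt = self.add_const(self.neg(self.lt(u, v, bitlen)), 1)
        not_gt = self.add_const(self.neg(self.lt(v, u, bitlen)), 1)
        return self.mul(not_lt, not_gt)

    def smin(self, u: SharedValue, v: SharedValue, bitlen: int | None = None) -> SharedValue:
        """Shared min(u, v) = u*eps + v*(1-eps) with eps = (u < v)."""
        self._gate("smin")
        eps = self.lt(u, v, bitlen)
        return self.add(self.mul(eps, u), self.sub(v, self.mul(eps, v)))

    def smax(self, u: SharedValue, v: SharedValue, bitlen: int | None = None) -> SharedValue:
        """Shared max(u, v) = v*eps + u*(1-eps) with eps = (u < v)."""
        self._gate("smax")
        eps = self.lt(u, v, bitlen)
        return self.add(self.mul(eps, v), self.sub(u, self.mul(eps, u)))

    # -- preprocessing cost model ------------------------------------------
    @staticmethod
    def lt_cost(bitlen: int) -> dict[str, int]:
        """Exact dealer-tape consumption of one lt at the given bit length."""
        return {"triples": 2 * bitlen - 1, "random_bits": bitlen, "bounded_masks": 1}
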