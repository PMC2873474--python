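"""RNA secondary-structure well-definedness via abstract shapes.

The quantity of interest is the Boltzmann probability of a transcript's
dominant level-5 abstract shape — the accumulated probability of all foldings
sharing that shape — compared against same-length genome windows whose
dominant shape is the same, summarized as a Z-score
``(Prob(t,p) - E(p,n)) / S(p,n)``.

Folding uses a compact nearest-neighbour energy model (stacking energies plus
affine hairpin/interior/multiloop penalties, minimum hairpin loop 3, interior
loops capped at ``max_interior`` unpaired nt).  The shape probability is
estimated by stochastic traceback sampling from a McCaskill-style partition
function; the same energy function drives an exhaustive structure enumerator
(`enumerate_structures` / `structure_energy`) that serves as an exact
reference at small sequence lengths.  Partition-function arithmetic uses
extended precision (longdouble) so that long GC-rich helices do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

# nearest-neighbour stacking energies, kcal/mol: key (pair(i,j), pair(i+1,j-1))
# with a pair written 5'-base + 3'-base of the enclosing pair
STACKING = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "GC"): -2.24,
    ("AU", "CG"): -2.08, ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "GC"): -2.35,
    ("UA", "CG"): -2.11, ("UA", "GU"): -1.00, ("UA", "UG"): -1.27,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "GC"): -3.26,
    ("CG", "CG"): -2.36, ("CG", "GU"): -1.41, ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24, ("GC", "GC"): -3.42,
    ("GC", "CG"): -3.26, ("GC", "GU"): -1.53, ("GC", "UG"): -2.51,
    ("GU", "AU"): -1.27, ("GU", "UA"): -1.36, ("GU", "GC"): -2.51,
    ("GU", "CG"): -2.11, ("GU", "GU"): -0.50, ("GU", "UG"): 1.29,
    ("UG", "AU"): -1.00, ("UG", "UA"): -0.55, ("UG", "GC"): -1.53,
    ("UG", "CG"): -1.41, ("UG", "GU"): 0.30, ("UG", "UG"): -0.50,
}

ALLOWED_PAIRS = frozenset(p for p, _ in STACKING)


@dataclass
class EnergyModel:
    stacking: dict = field(default_factory=lambda: dict(STACKING))
    hairpin_a: float = 5.4       # hairpin closing penalty at loop size 3
    hairpin_b: float = 0.25      # per extra unpaired nt
    interior_a: float = 3.2      # interior/bulge loop base penalty
    interior_b: float = 0.45     # per unpaired nt
    max_interior: int = 8        # max unpaired nt in an interior/bulge loop
    ml_a: float = 3.4            # multiloop closing
    ml_b: float = 0.4            # per branch (the closing pair counts as one)
    ml_c: float = 0.1            # per unpaired multiloop nt
    min_hairpin: int = 3
    temperature: float = 37.0    # Celsius

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * (273.15 + self.temperature)

    def hairpin(self, loop: int) -> float:
        return self.hairpin_a + self.hairpin_b * (loop - self.min_hairpin)

    def interior(self, unpaired: int) -> float:
        if unpaired > self.max_interior:
            return float("inf")
        return self.interior_a + self.interior_b * unpaired

    def can_pair(self, a: str, b: str) -> bool:
        return a + b in ALLOWED_PAIRS


DEFAULT_MODEL = EnergyModel()


def to_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError("sequence contains non-ACGT/U characters")
    return seq


# ---------------------------------------------------------------------------
# dot-bracket helpers and level-5 abstract shapes

def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def pairs_to_dotbracket(pairs, n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def _pair_tree(pairs) -> list:
    """Nesting forest: each node is (i, j, children)."""
    root: list = []
    stack = [(-1, 10**12, root)]
    for i, j in sorted(pairs):
        while i > stack[-1][1]:
            stack.pop()
        node = (i, j, [])
        stack[-1][2].append(node)
        stack.append(node)
    return root


def abstract_shape(structure: str) -> str:
    """Level-5 abstract shape of a dot-bracket structure: helix nestings
    collapse, unpaired regions drop, every hairpin becomes ``[]``; a
    structure without any pair maps to ``_``."""
    forest = _pair_tree(parse_dotbracket(structure))
    if not forest:
        return "_"

    def shape(node) -> str:
        _, _, children = node
        if not children:
            return "[]"
        if len(children) == 1:
            return shape(children[0])
        return "[" + "".join(shape(c) for c in children) + "]"

    return "".join(shape(t) for t in forest)


# ---------------------------------------------------------------------------
# structure energy (shared definition for enumeration and sampling checks)

def structure_energy(sequence: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Free energy of one secondary structure under the model; ``inf`` for
    structures outside the model space (oversized interior loops)."""
    seq = to_rna(sequence)
    for i, j in pairs:
        if not model.can_pair(seq[i], seq[j]):
            return float("inf")
        if j - i - 1 < model.min_hairpin:
            return float("inf")
    energy = 0.0
    forest = _pair_tree(pairs)
    stack = list(forest)
    while stack:
        i, j, children = stack.pop()
        stack.extend(children)
        if not children:
            energy += model.hairpin(j - i - 1)
        elif len(children) == 1:
            k, l, _ = children[0]
            u = (k - i - 1) + (j - l - 1)
            if u == 0:
                energy += model.stacking[(seq[i] + seq[j], seq[k] + seq[l])]
            else:
                e = model.interior(u)
                if e == float("inf"):
                    return float("inf")
                energy += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l, _ in children)
            energy += (model.ml_a + model.ml_b * (len(children) + 1)
                       + model.ml_c * unpaired)
    return energy


def enumerate_structures(sequence: str,
                         model: EnergyModel = DEFAULT_MODEL) -> list[list[tuple[int, int]]]:
    """All nested secondary structures (pair lists) with the model's pairing
    rules and minimum hairpin size.  Exponential; intended for short
    sequences as an exact reference."""
    seq = to_rna(sequence)
    n = len(seq)
    memo: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j - i + 1 <= model.min_hairpin:
            return [[]]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [s for s in rec(i + 1, j)]
        for l in range(i + model.min_hairpin + 1, j + 1):
            if not model.can_pair(seq[i], seq[l]):
                continue
            for inner in rec(i + 1, l - 1):
                for rest in rec(l + 1, j):
                    out.append([(i, l)] + inner + rest)
        memo[key] = out
        return out

    return rec(0, n - 1) if n else [[]]


def exact_shape_probabilities(sequence: str,
                              model: EnergyModel = DEFAULT_MODEL) -> dict[str, float]:
    """Exact Boltzmann shape probabilities by exhaustive enumeration."""
    seq = to_rna(sequence)
    rt = model.rt
    weights: dict[str, float] = {}
    total = 0.0
    for pairs in enumerate_structures(seq, model):
        e = structure_energy(seq, pairs, model)
        if e == float("inf"):
            continue
        w = float(np.exp(np.longdouble(-e / rt)))
        total += w
        shape = abstract_shape(pairs_to_dotbracket(pairs, len(seq)))
        weights[shape] = weights.get(shape, 0.0) + w
    return {s: w / total for s, w in weights.items()}


# ---------------------------------------------------------------------------
# McCaskill-style partition function with stochastic traceback

class PartitionFunction:
    """Inside matrices over the nested-structure ensemble of one sequence."""

    def __init__(self, sequence: str, model: EnergyModel = DEFAULT_MODEL):
        self.seq = to_rna(sequence)
        self.model = model
        self.n = len(self.seq)
        self._fill()

    def _fill(self) -> None:
        n, m, seq = self.n, self.model, self.seq
        rt = m.rt
        ld = np.longdouble
        h = m.min_hairpin
        self.w_mlb = ld(np.exp(-m.ml_b / rt))
        self.w_mlclose = ld(np.exp(-(m.ml_a + m.ml_b) / rt))
        self.mc_pow = np.exp(-m.ml_c * np.arange(n + 1) / rt).astype(np.longdouble)
        canp = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + h + 1, n):
                canp[i, j] = m.can_pair(seq[i], seq[j])
        self.canp = canp
        Qb = np.zeros((n, n), dtype=np.longdouble)
        Qm1 = np.zeros((n, n), dtype=np.longdouble)
        Qm = np.zeros((n, n), dtype=np.longdouble)
        for d in range(h + 1, n):
            for i in range(0, n - d):
                j = i + d
                if canp[i, j]:
                    w = ld(np.exp(-m.hairpin(j - i - 1) / rt))
                    # interior loops / stacks, bounded unpaired total
                    for k in range(i + 1, min(i + 2 + m.max_interior, j - h - 1)):
                        left = k - i - 1
                        lmin = max(k + h + 1, j - 1 - (m.max_interior - left))
                        for l in range(lmin, j):
                            if not canp[k, l]:
                                continue
                            u = left + (j - l - 1)
                            if u == 0:
                                e = m.stacking[(seq[i] + seq[j], seq[k] + seq[l])]
                            else:
                                e = m.interior(u)
                            w += ld(np.exp(-e / rt)) * Qb[k, l]
                    # multiloop: >= 2 branches inside
                    if j - i >= 2 * h + 4:
                        acc = np.dot(Qm[i + 1, i + 1:j - h - 1],
                                     Qm1[i + 2:j - h, j - 1])
                        w += self.w_mlclose * acc
                    Qb[i, j] = w
                # Qm1: one branch starting exactly at i
                if j >= i + h + 1:
                    ls = np.arange(i + h + 1, j + 1)
                    Qm1[i, j] = self.w_mlb * np.dot(Qb[i, i + h + 1:j + 1],
                                                    self.mc_pow[j - ls])
                    # Qm: >= 1 branch in [i, j]
                    acc = np.longdouble(0.0)
                    for k in range(i, j - h):
                        t = self.mc_pow[k - i]
                        if k > i:
                            t = t + Qm[i, k - 1]
                        acc += t * Qm1[k, j]
                    Qm[i, j] = acc
        self.Qb, self.Qm1, self.Qm = Qb, Qm1, Qm
        Q = np.ones(n + 1, dtype=np.longdouble)   # Q[j+1] covers prefix [0..j]
        for j in range(n):
            tot = Q[j]
            for i in range(0, j - h):
                if canp[i, j]:
                    tot += Q[i] * Qb[i, j]
            Q[j + 1] = tot
        self.Q = Q

    @property
    def partition(self) -> float:
        return float(self.Q[self.n])

    # --- stochastic traceback -------------------------------------------

    def sample(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        n, h = self.n, self.model.min_hairpin
        pairs: list[tuple[int, int]] = []
        tasks: list[tuple] = [("ext", n - 1)]
        while tasks:
            task = tasks.pop()
            kind = task[0]
            if kind == "ext":
                j = task[1]
                if j < 0:
                    continue
                r = np.longdouble(rng.random()) * self.Q[j + 1]
                acc = self.Q[j].copy()
                if r <= acc:
                    tasks.append(("ext", j - 1))
                    continue
                done = False
                for i in range(0, j - h):
                    if not self.canp[i, j]:
                        continue
                    acc = acc + self.Q[i] * self.Qb[i, j]
                    if r <= acc:
                        pairs.append((i, j))
                        tasks.append(("qb", i, j))
                        tasks.append(("ext", i - 1))
                        done = True
                        break
                if not done:   # numerical leftovers: fall back to last option
                    tasks.append(("ext", j - 1))
            elif kind == "qb":
                i, j = task[1], task[2]
                m, seq, rt = self.model, self.seq, self.model.rt
                r = np.longdouble(rng.random()) * self.Qb[i, j]
                acc = np.longdouble(np.exp(-m.hairpin(j - i - 1) / rt))
                if r <= acc:
                    continue
                done = False
                for k in range(i + 1, min(i + 2 + m.max_interior, j - h - 1)):
                    left = k - i - 1
                    lmin = max(k + h + 1, j - 1 - (m.max_interior - left))
                    for l in range(lmin, j):
                        if not self.canp[k, l]:
                            continue
                        u = left + (j - l - 1)
                        if u == 0:
                            e = m.stacking[(seq[i] + seq[j], seq[k] + seq[l])]
                        else:
                            e = m.interior(u)
                        acc = acc + np.longdouble(np.exp(-e / rt)) * self.Qb[k, l]
                        if r <= acc:
                            pairs.append((k, l))
                            tasks.append(("qb", k, l))
                            done = True
                            break
                    if done:
                        break
                if done:
                    continue
                for hh in range(i + 2, j - h):
                    acc = acc + (self.w_mlclose * self.Qm[i + 1, hh - 1]
                                 * self.Qm1[hh, j - 1])
                    if r <= acc:
                        tasks.append(("qm", i + 1, hh - 1))
                        tasks.append(("qm1", hh, j - 1))
                        done = True
                        break
                if not done:
                    continue   # numerical leftovers: keep hairpin
            elif kind == "qm":
                i, j = task[1], task[2]
                r = np.longdouble(rng.random()) * self.Qm[i, j]
                acc = np.longdouble(0.0)
                for k in range(i, j - h):
                    acc = acc + self.mc_pow[k - i] * self.Qm1[k, j]
                    if r <= acc:
                        tasks.append(("qm1", k, j))
                        break
                    if k > i:
                        acc = acc + self.Qm[i, k - 1] * self.Qm1[k, j]
                        if r <= acc:
                            tasks.append(("qm", i, k - 1))
                            tasks.append(("qm1", k, j))
                            break
            else:  # qm1
                i, j = task[1], task[2]
                r = np.longdouble(rng.random()) * self.Qm1[i, j]
                acc = np.longdouble(0.0)
                for l in range(i + h + 1, j + 1):
                    acc = acc + (self.w_mlb * self.Qb[i, l]
                                 * self.mc_pow[j - l])
                    if r <= acc:
                        pairs.append((i, l))
                        tasks.append(("qb", i, l))
                        break
        return sorted(pairs)


# ---------------------------------------------------------------------------
# shape profiles, background distributions and Z-scores

@dataclass
class ShapeProfile:
    sequence: str
    shape: str                 # dominant level-5 shape
    prob: float                # estimated Prob(t, p)
    mfe_representative: str    # lowest-energy sampled structure of that shape
    n: int
    k: int
    rng_seed: int
    shape_counts: dict = field(default_factory=dict)


@dataclass
class ShapeBackground:
    shape: str
    n: int
    mean: float | None
    sd: float | None
    n_windows_used: int
    sampling_policy: str
    rng_seed: int
    values: list[float] = field(default_factory=list)
    error: str | None = None


@dataclass
class ZScoreResult:
    contig_id: str
    z: float
    profile: ShapeProfile
    background: ShapeBackground


def shape_probabilities(sequence: str, model: EnergyModel = DEFAULT_MODEL,
                        k: int = 1000, seed: int = 0) -> ShapeProfile:
    """Dominant shape and its estimated Boltzmann probability from ``k``
    stochastically sampled structures.  Ties break toward the
    lexicographically smaller shape string."""
    if len(sequence) < 10:
        raise ValueError("sequence shorter than 10 nt")
    seq = to_rna(sequence)
    pf = PartitionFunction(seq, model)
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    best: dict[str, tuple[float, str]] = {}
    for _ in range(k):
        pairs = pf.sample(rng)
        db = pairs_to_dotbracket(pairs, len(seq))
        shape = abstract_shape(db)
        counts[shape] = counts.get(shape, 0) + 1
        e = structure_energy(seq, pairs, model)
        if shape not in best or e < best[shape][0]:
            best[shape] = (e, db)
    dominant = min(counts, key=lambda s: (-counts[s], s))
    return ShapeProfile(seq, dominant, counts[dominant] / k,
                        best[dominant][1], len(seq), k, seed,
                        {s: c / k for s, c in counts.items()})


def background_distribution(genome, strand: str, shape: str, n: int,
                            policy: str = "random", n_windows: int = 500,
                            seed: int = 0, k: int = 200,
                            model: EnergyModel = DEFAULT_MODEL,
                            replicon: str | None = None) -> ShapeBackground:
    """Distribution of Prob(w, p) over same-strand genome windows of length
    ``n`` whose dominant shape is also ``p``.

    ``genome`` may be a :class:`srnacall.types.Genome` or a plain sequence
    string.  Policies: ``all`` windows, ``strided``, or a seeded ``random``
    subsample of ``n_windows`` start positions (default).
    """
    if isinstance(genome, str):
        source = genome
    else:
        rep = genome.replicons[0] if replicon is None else genome[replicon]
        source = rep.sequence
    if len(source) <= n:
        raise ValueError("genome shorter than window length")
    rng = np.random.default_rng([seed, 17])
    max_start = len(source) - n
    if policy == "all":
        starts = np.arange(max_start + 1)
    elif policy == "strided":
        step = max(1, (max_start + 1) // max(1, n_windows))
        starts = np.arange(0, max_start + 1, step)
    elif policy == "random":
        n_take = min(n_windows, max_start + 1)
        starts = np.sort(rng.choice(max_start + 1, size=n_take, replace=False))
    else:
        raise ValueError(f"unknown sampling policy {policy!r}")
    values = []
    from .types import revcomp
    for idx, s0 in enumerate(starts):
        sub = source[int(s0):int(s0) + n]
        if strand == "-":
            sub = revcomp(sub)
        prof = shape_probabilities(sub, model, k=k, seed=int(seed * 1_000_003
                                                             + idx) % (2**31))
        if prof.shape == shape:
            values.append(prof.prob)
    if len(values) < 2:
        return ShapeBackground(shape, n, None, None, len(values), policy,
                               seed, values,
                               error="fewer than 2 windows share the shape")
    arr = np.array(values)
    return ShapeBackground(shape, n, float(arr.mean()),
                           float(arr.std(ddof=1)), len(values), policy, seed,
                           values)


def zscore(profile: ShapeProfile, background: ShapeBackground,
           contig_id: str = "") -> ZScoreResult:
    if background.error:
        raise ValueError(f"undefined background: {background.error}")
    if profile.shape != background.shape:
        raise ValueError("profile and background shapes differ")
    if not background.sd or background.sd <= 0:
        raise ValueError("background standard deviation is zero")
    z = (profile.prob - background.mean) / background.sd
    return ZScoreResult(contig_id, float(z), profile, background)
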