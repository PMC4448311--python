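"""Lightweight stochastic context-free grammars for RNA folding spaces.

A :class:`Grammar` assigns probabilities to derivations; for RNA-folding
grammars every derivation corresponds to a nested (pseudoknot-free)
secondary structure, so the sequence-conditioned distribution over
derivations is a probabilistic model of the folding space.  This module
implements the exact dynamic programs on that model:

* :func:`inside_logZ` — total derivation probability (natural log),
* :func:`derivation_entropy` — exact Shannon entropy of the conditional
  derivation distribution, H = ln Z − E[ln P(π) | π derives the sequence],
  computed by carrying the conditional expected log-probability alongside
  the inside mass (no enumeration),
* :func:`pair_probabilities` — posterior base-pairing matrix P_ij via
  inside–outside,
* :func:`cyk_predict` — a maximum-probability derivation's structure,
* :func:`sample_structures_scfg` — stochastic traceback sampling,
* :func:`estimate_parameters` — counting maximum likelihood from
  structure-annotated training sequences.

All arithmetic is in natural-log space so sequences of several hundred
nucleotides do not underflow.  For structurally unambiguous grammars
(one derivation per structure, e.g. the Knudsen–Hein/G6 shape) the
derivation entropy equals the structure entropy; for ambiguous grammars
it is the entropy over derivations, which is the operational definition
used throughout this package.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGU"
_NT_OF_CHAR = {c: i for i, c in enumerate(ALPHABET)}

#: Watson-Crick plus wobble, the default pairing rule set.
WATSON_CRICK_GU = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

_EPS_TOKENS = {"eps", "epsilon", "ε", "_"}
_NEG_INF = float("-inf")


class GrammarError(ValueError):
    """Malformed grammar definition or invariant violation."""


class ZeroProbabilityError(ArithmeticError):
    """The grammar assigns zero probability to the sequence.

    Raised instead of returning ``-inf`` so callers can distinguish a
    non-derivable sequence from a numerical failure.
    """


def encode_sequence(seq: str) -> np.ndarray:
    """Map an RNA/DNA string to integer codes, folding case and T→U.

    Any character outside {A,C,G,U,T} is an error; IUPAC ambiguity codes
    are rejected because the grammars emit only the four bases.
    """
    s = seq.upper().replace("T", "U")
    try:
        return np.array([_NT_OF_CHAR[c] for c in s], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


def normalize_sequence(seq: str) -> str:
    encode_sequence(seq)  # validation
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# Secondary structures


class SecondaryStructure:
    """A non-crossing base-pair set with its dot-bracket rendering.

    Pairs are 1-based ``(i, j)`` with ``i < j``; the dot-bracket string and
    pair set are kept mutually consistent and validated on construction.
    """

    __slots__ = ("dotbracket", "pairs")

    def __init__(self, dotbracket: str):
        pairs = self._parse(dotbracket)
        self.dotbracket = dotbracket
        self.pairs = pairs

    @staticmethod
    def _parse(db: str) -> frozenset[tuple[int, int]]:
        stack: list[int] = []
        pairs = set()
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced dot-bracket at position {pos}")
                pairs.add((stack.pop(), pos))
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket: unclosed '('")
        return frozenset(pairs)

    @classmethod
    def from_pairs(cls, length: int, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        chars = ["."] * length
        seen: set[int] = set()
        for i, j in sorted(pairs):
            if not (1 <= i < j <= length):
                raise ValueError(f"pair {(i, j)} out of bounds for length {length}")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: {(i, j)}")
            seen.update((i, j))
            chars[i - 1] = "("
            chars[j - 1] = ")"
        ss = cls("".join(chars))
        if ss.pairs != frozenset((i, j) for i, j in pairs):
            raise ValueError("crossing base pairs (pseudoknots are not representable)")
        return ss

    def __len__(self) -> int:
        return len(self.dotbracket)

    def __eq__(self, other) -> bool:
        return isinstance(other, SecondaryStructure) and self.dotbracket == other.dotbracket

    def __hash__(self) -> int:
        return hash(self.dotbracket)

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.dotbracket!r})"


# ---------------------------------------------------------------------------
# Grammar definition


@dataclass(frozen=True)
class Rule:
    """One production.  ``kind`` is one of:

    - ``emit``:   V -> x          (terminal, unpaired base)
    - ``pair``:   V -> x W y      (paired bases flanking a nonterminal)
    - ``binary``: V -> W Z
    - ``unit``:   V -> W
    - ``empty``:  V -> ε
    """

    lhs: str
    kind: str
    prob: float
    terminal: str = ""          # emit
    left: str = ""              # pair: left terminal
    right: str = ""             # pair: right terminal
    child: str = ""             # pair/unit inner nonterminal
    children: tuple[str, str] = ()  # binary

    def rhs_text(self) -> str:
        if self.kind == "emit":
            return self.terminal.lower()
        if self.kind == "pair":
            return f"{self.left.lower()} {self.child} {self.right.lower()}"
        if self.kind == "binary":
            return " ".join(self.children)
        if self.kind == "unit":
            return self.child
        return "eps"


def _make_rule(lhs: str, tokens: Sequence[str], prob: float) -> Rule:
    def is_term(t: str) -> bool:
        return t.lower() in ("a", "c", "g", "u", "t") and t.islower()

    toks = list(tokens)
    if len(toks) == 1 and toks[0].lower() in _EPS_TOKENS:
        return Rule(lhs, "empty", prob)
    if len(toks) == 1 and is_term(toks[0]):
        return Rule(lhs, "emit", prob, terminal=normalize_sequence(toks[0].upper()))
    if len(toks) == 1:
        return Rule(lhs, "unit", prob, child=toks[0])
    if len(toks) == 2 and not any(is_term(t) for t in toks):
        return Rule(lhs, "binary", prob, children=(toks[0], toks[1]))
    if len(toks) == 3 and is_term(toks[0]) and is_term(toks[2]) and not is_term(toks[1]):
        return Rule(
            lhs,
            "pair",
            prob,
            left=normalize_sequence(toks[0].upper()),
            right=normalize_sequence(toks[2].upper()),
            child=toks[1],
        )
    raise GrammarError(f"unrecognized production: {lhs} -> {' '.join(toks)}")


class Grammar:
    """An SCFG over the four ribonucleotides.

    Parameters
    ----------
    rules:
        Productions in a fixed order (the order is the CYK tie-break order).
    start:
        Start nonterminal; defaults to the LHS of the first rule.
    allowed_pairs:
        Unordered set of permitted base pairings (as ordered 2-tuples, both
        orientations).  Pair-emission mass on a disallowed combination is an
        error.
    min_hairpin:
        Minimum number of enclosed positions for any base pair (0 is
        grammar-faithful; 3 mimics the usual steric constraint).
    """

    def __init__(
        self,
        rules: Sequence[Rule],
        start: str | None = None,
        allowed_pairs: frozenset[tuple[str, str]] = WATSON_CRICK_GU,
        min_hairpin: int = 0,
        source_hash: str = "",
    ):
        if not rules:
            raise GrammarError("grammar has no rules")
        self.rules = tuple(rules)
        self.start = start if start is not None else rules[0].lhs
        self.allowed_pairs = frozenset(allowed_pairs)
        self.min_hairpin = int(min_hairpin)
        self.source_hash = source_hash
        nts: list[str] = []
        for r in self.rules:
            if r.lhs not in nts:
                nts.append(r.lhs)
        self.nonterminals = tuple(nts)
        self._validate()
        self._compiled: _Compiled | None = None

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        known = set(self.nonterminals)
        if self.start not in known:
            raise GrammarError(f"start symbol {self.start!r} has no productions")
        for r in self.rules:
            for ref in ((r.child,) if r.child else r.children):
                if ref and ref not in known:
                    raise GrammarError(f"unknown nonterminal {ref!r} in {r.lhs} -> {r.rhs_text()}")
            if not (0.0 <= r.prob <= 1.0):
                raise GrammarError(f"probability out of [0,1] in {r.lhs} -> {r.rhs_text()}")
            if r.kind == "pair" and r.prob > 0 and (r.left, r.right) not in self.allowed_pairs:
                raise GrammarError(
                    f"pair emission {r.left}-{r.right} not in allowed pairs "
                    f"(rule {r.lhs} -> {r.rhs_text()})"
                )
        for v in self.nonterminals:
            total = sum(r.prob for r in self.rules if r.lhs == v)
            if abs(total - 1.0) > 1e-9:
                raise GrammarError(
                    f"productions of {v} sum to {total:.12g}, expected 1"
                )

    @classmethod
    def from_rule_probs(
        cls,
        rule_probs: Sequence[tuple[str, str, float]],
        **kwargs,
    ) -> "Grammar":
        """Build from ``(lhs, rhs-text, prob)`` triples (rhs whitespace-split)."""
        rules = [_make_rule(lhs, rhs.split(), p) for lhs, rhs, p in rule_probs]
        return cls(rules, **kwargs)

    # -- compiled form -----------------------------------------------------

    @property
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def config_text(self) -> str:
        """Serialize in the plain-text config format accepted by load_grammar."""
        lines = []
        pairs = sorted({tuple(sorted(p)) for p in self.allowed_pairs})
        lines.append("@pairs " + " ".join(a + b for a, b in pairs))
        if self.min_hairpin:
            lines.append(f"@min_hairpin {self.min_hairpin}")
        for r in self.rules:
            lines.append(f"{r.lhs} -> {r.rhs_text()} : {r.prob!r}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        return f"Grammar(start={self.start!r}, |rules|={len(self.rules)})"


def load_grammar(path: str | Path) -> Grammar:
    """Read a grammar config: one ``LHS -> RHS : prob`` production per line.

    Terminals are lowercase a/c/g/u (t accepted, mapped to u); ``eps``
    denotes the empty string; ``#`` starts a comment.  Optional directives:
    ``@pairs au cg gu`` (unordered allowed pairs) and ``@min_hairpin k``.
    Per-LHS probability sums off by more than 1e-6 are an error; smaller
    violations are renormalized with a warning.  The file's SHA-256 prefix
    is stored on the grammar for provenance.
    """
    path = Path(path)
    text = path.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    allowed: set[tuple[str, str]] | None = None
    min_hp = 0
    triples: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@pairs"):
            allowed = set()
            for tok in line.split()[1:]:
                tok = tok.upper().replace("T", "U")
                if len(tok) != 2 or any(c not in ALPHABET for c in tok):
                    raise GrammarError(f"line {lineno}: bad pair token {tok!r}")
                allowed.add((tok[0], tok[1]))
                allowed.add((tok[1], tok[0]))
            continue
        if line.startswith("@min_hairpin"):
            min_hp = int(line.split()[1])
            continue
        if "->" not in line or ":" not in line:
            raise GrammarError(f"line {lineno}: expected 'LHS -> RHS : prob', got {raw!r}")
        head, prob_text = line.rsplit(":", 1)
        lhs, rhs = head.split("->", 1)
        lhs = lhs.strip()
        try:
            prob = float(prob_text)
        except ValueError:
            raise GrammarError(f"line {lineno}: bad probability {prob_text.strip()!r}") from None
        triples.append((lhs, rhs.strip(), prob))
    if not triples:
        raise GrammarError(f"{path}: no productions found")

    # normalization policy: <=1e-9 silently fine, <=1e-6 renormalize + warn
    sums: dict[str, float] = {}
    for lhs, _, p in triples:
        sums[lhs] = sums.get(lhs, 0.0) + p
    fixed: list[tuple[str, str, float]] = []
    for lhs, rhs, p in triples:
        dev = abs(sums[lhs] - 1.0)
        if dev > 1e-6:
            raise GrammarError(
                f"{path}: productions of {lhs} sum to {sums[lhs]:.12g} (>1e-6 off 1)"
            )
        if dev > 1e-9:
            p = p / sums[lhs]
        fixed.append((lhs, rhs, p))
    for lhs, total in sums.items():
        if 1e-9 < abs(total - 1.0) <= 1e-6:
            warnings.warn(
                f"{path}: renormalized productions of {lhs} (sum {total:.12g})",
                stacklevel=2,
            )
    kwargs = {"min_hairpin": min_hp, "source_hash": digest}
    if allowed is not None:
        kwargs["allowed_pairs"] = frozenset(allowed)
    return Grammar.from_rule_probs(fixed, **kwargs)


# ---------------------------------------------------------------------------
# Compiled grammar: grouped, indexed, epsilon-closed


class _Compiled:
    """Grammar preprocessed for the dynamic programs.

    Epsilon-deriving nonterminals are closed out: a binary rule with an
    ε-deriving child behaves, on non-empty spans, like a unit rule whose
    probability is scaled by the child's ε mass ("effective unit").  The
    effective-unit graph must be acyclic (finite derivations of a finite
    string), which is checked here.
    """

    def __init__(self, g: Grammar):
        self.grammar = g
        self.K = len(g.nonterminals)
        self.idx = {v: i for i, v in enumerate(g.nonterminals)}
        K = self.K

        self.emit_logp = np.full((K, 4), _NEG_INF)
        self.emit_rule: dict[tuple[int, int], Rule] = {}
        pair_mats: dict[tuple[int, int], np.ndarray] = {}
        pair_order: list[tuple[int, int]] = []
        self.pair_rule: dict[tuple[int, int, int, int], Rule] = {}
        self.binary: list[tuple[int, int, int, float, Rule]] = []
        unit: list[tuple[int, int, float, Rule]] = []
        empty: dict[int, float] = {}
        for r in g.rules:
            v = self.idx[r.lhs]
            if r.kind == "emit":
                x = _NT_OF_CHAR[r.terminal]
                if np.isfinite(self.emit_logp[v, x]):
                    raise GrammarError(f"duplicate emission {r.lhs} -> {r.terminal}")
                self.emit_logp[v, x] = math.log(r.prob) if r.prob > 0 else _NEG_INF
                self.emit_rule[(v, x)] = r
            elif r.kind == "pair":
                w = self.idx[r.child]
                key = (v, w)
                if key not in pair_mats:
                    pair_mats[key] = np.full((4, 4), _NEG_INF)
                    pair_order.append(key)
                x, y = _NT_OF_CHAR[r.left], _NT_OF_CHAR[r.right]
                if np.isfinite(pair_mats[key][x, y]):
                    raise GrammarError(f"duplicate pair emission {r.lhs} -> {r.rhs_text()}")
                pair_mats[key][x, y] = math.log(r.prob) if r.prob > 0 else _NEG_INF
                self.pair_rule[(v, w, x, y)] = r
            elif r.kind == "binary":
                w, z = (self.idx[c] for c in r.children)
                self.binary.append((v, w, z, math.log(r.prob) if r.prob > 0 else _NEG_INF, r))
            elif r.kind == "unit":
                unit.append((v, self.idx[r.child], math.log(r.prob) if r.prob > 0 else _NEG_INF, r))
            else:  # empty
                empty[v] = empty.get(v, 0.0) + r.prob
        self.pair_groups = [(v, w, pair_mats[(v, w)]) for v, w in pair_order]
        self.unit = unit

        # epsilon closure: total mass, expected log-prob, and max-derivation
        # log-prob of deriving the empty string from each nonterminal.
        eps_mass = np.zeros(K)
        eps_avg = np.zeros(K)  # Σ_π P(π) ln P(π) over ε-derivations (un-normalized)
        eps_max = np.full(K, _NEG_INF)
        for _ in range(K + 1):
            new_mass = np.zeros(K)
            new_avg = np.zeros(K)
            new_max = np.full(K, _NEG_INF)
            for v, p in empty.items():
                new_mass[v] += p
                new_avg[v] += p * math.log(p)
                new_max[v] = max(new_max[v], math.log(p))
            for v, w, lp, _r in unit:
                if eps_mass[w] > 0 and np.isfinite(lp):
                    p = math.exp(lp)
                    new_mass[v] += p * eps_mass[w]
                    new_avg[v] += p * (eps_mass[w] * lp + eps_avg[w])
                    new_max[v] = max(new_max[v], lp + eps_max[w])
            for v, w, z, lp, _r in self.binary:
                if eps_mass[w] > 0 and eps_mass[z] > 0 and np.isfinite(lp):
                    p = math.exp(lp)
                    m = eps_mass[w] * eps_mass[z]
                    new_mass[v] += p * m
                    new_avg[v] += p * (
                        m * lp + eps_avg[w] * eps_mass[z] + eps_mass[w] * eps_avg[z]
                    )
                    new_max[v] = max(new_max[v], lp + eps_max[w] + eps_max[z])
            if (
                np.allclose(new_mass, eps_mass, atol=1e-15)
                and np.allclose(new_avg, eps_avg, atol=1e-15)
            ):
                eps_mass, eps_avg, eps_max = new_mass, new_avg, new_max
                break
            eps_mass, eps_avg, eps_max = new_mass, new_avg, new_max
        else:
            raise GrammarError("cyclic epsilon derivations (grammar not acyclic)")
        with np.errstate(divide="ignore", invalid="ignore"):
            self.eps_logmass = np.where(eps_mass > 0, np.log(np.where(eps_mass > 0, eps_mass, 1.0)), _NEG_INF)
            # conditional expected log-prob of an ε-derivation
            self.eps_A = np.where(eps_mass > 0, eps_avg / np.where(eps_mass > 0, eps_mass, 1.0), 0.0)
        self.eps_logmax = eps_max
        self.has_epsilon = bool((eps_mass > 0).any())

        # effective units: true unit rules + binary rules with an ε child.
        # entries: (v, w, log_mass_scale, a_const, log_max_scale, rule, eps_side)
        eff: list[tuple[int, int, float, float, float, Rule, str]] = []
        for v, w, lp, r in unit:
            eff.append((v, w, lp, lp, lp, r, ""))
        for v, w, z, lp, r in self.binary:
            if eps_mass[z] > 0 and np.isfinite(lp):
                eff.append(
                    (v, w, lp + self.eps_logmass[z], lp + self.eps_A[z],
                     lp + self.eps_logmax[z], r, "right")
                )
            if eps_mass[w] > 0 and np.isfinite(lp):
                eff.append(
                    (v, z, lp + self.eps_logmass[w], lp + self.eps_A[w],
                     lp + self.eps_logmax[w], r, "left")
                )
        self.eff_units = eff

        # topological order over effective-unit dependencies (child first)
        deps: dict[int, set[int]] = {i: set() for i in range(K)}
        for v, w, *_ in eff:
            if v != w:
                deps[v].add(w)
            else:
                raise GrammarError("self-referential unit/epsilon cycle")
        order: list[int] = []
        state = [0] * K  # 0 unvisited, 1 in stack, 2 done

        def visit(u: int) -> None:
            if state[u] == 1:
                raise GrammarError("cyclic unit/epsilon dependencies in grammar")
            if state[u] == 2:
                return
            state[u] = 1
            for d in deps[u]:
                visit(d)
            state[u] = 2
            order.append(u)

        for u in range(K):
            visit(u)
        self.topo = order  # children before parents

        # per-nonterminal grouped views for the DP inner loop
        self.pairs_of = [[pg for pg in self.pair_groups if pg[0] == v] for v in range(K)]
        self.binaries_of = [
            [b for b in self.binary if b[0] == v and np.isfinite(b[3])] for v in range(K)
        ]
        self.effs_of = [
            [e for e in eff if e[0] == v and np.isfinite(e[2])] for v in range(K)
        ]


# ---------------------------------------------------------------------------
# Numerics helpers


def _wlogsum(lm: np.ndarray, av: np.ndarray | None, axis: int):
    """Log-sum-exp along ``axis`` plus the mass-weighted mean of ``av``.

    ``av`` carries the conditional expected log-probability of each
    contribution; the weighted mean keeps it O(n) in magnitude, which is
    the trick that lets the entropy DP run in plain log space.
    """
    m = np.max(lm, axis=axis)
    finite = np.isfinite(m)
    shift = np.where(finite, m, 0.0)
    e = np.exp(lm - np.expand_dims(shift, axis))
    s = e.sum(axis=axis)
    safe_s = np.where(s > 0, s, 1.0)
    tot = np.where(finite, shift + np.log(safe_s), _NEG_INF)
    if av is None:
        return tot, None
    avc = np.where(np.isfinite(lm), av, 0.0)
    w = e / np.expand_dims(safe_s, axis)
    a = (w * avc).sum(axis=axis)
    return tot, np.where(finite, a, 0.0)


@dataclass
class _Mask:
    """Structure constraint for training: which emissions are admissible."""

    unpaired_ok: np.ndarray  # (n,) bool
    pair_ok: np.ndarray      # (n, n) bool, [i, j-1] 0-based

    @classmethod
    def from_structure(cls, n: int, s: SecondaryStructure) -> "_Mask":
        if len(s) != n:
            raise ValueError("structure length does not match sequence")
        unp = np.ones(n, dtype=bool)
        pk = np.zeros((n, n), dtype=bool)
        for i, j in s.pairs:
            unp[i - 1] = False
            unp[j - 1] = False
            pk[i - 1, j - 1] = True
        return cls(unp, pk)


# ---------------------------------------------------------------------------
# Inside (sum / entropy) DP


def _inside(
    g: Grammar,
    seq_idx: np.ndarray,
    with_A: bool = False,
    mask: _Mask | None = None,
    dtype=np.float64,
):
    """Fill the inside chart; optionally carry the entropy accumulator.

    Returns ``(logI, A)`` of shape (K, n+1, n+1) indexed by half-open
    spans [i, j).  ``A[v, i, j]`` is E[ln P(π)] over derivations of the
    span from nonterminal v (0 where the mass is zero).
    """
    c = g.compiled
    n = len(seq_idx)
    K = c.K
    logI = np.full((K, n + 1, n + 1), _NEG_INF, dtype=dtype)
    A = np.zeros((K, n + 1, n + 1), dtype=dtype) if with_A else None
    emit_logp = c.emit_logp.astype(dtype)
    min_hp = g.min_hairpin

    for L in range(1, n + 1):
        i_arr = np.arange(0, n - L + 1)
        j_arr = i_arr + L
        for v in c.topo:
            lms: list[np.ndarray] = []
            avs: list[np.ndarray] = []
            if L == 1:
                lm = emit_logp[v, seq_idx[i_arr]].copy()
                if mask is not None:
                    lm = np.where(mask.unpaired_ok[i_arr], lm, _NEG_INF)
                lms.append(lm)
                avs.append(lm.copy())
            if L >= 2 and L - 2 >= min_hp:
                for _, w, mat in c.pairs_of[v]:
                    plog = mat.astype(dtype)[seq_idx[i_arr], seq_idx[j_arr - 1]]
                    if mask is not None:
                        plog = np.where(mask.pair_ok[i_arr, j_arr - 1], plog, _NEG_INF)
                    if L == 2:
                        child = dtype(c.eps_logmass[w])
                        child_a = dtype(c.eps_A[w])
                    else:
                        child = logI[w, i_arr + 1, j_arr - 1]
                        child_a = A[w, i_arr + 1, j_arr - 1] if with_A else None
                    lms.append(plog + child)
                    if with_A:
                        avs.append(plog + child_a)
            if L >= 2:
                m_arr = np.arange(1, L)
                iw = i_arr[:, None] + m_arr[None, :]
                for _, w, z, lp, _r in c.binaries_of[v]:
                    lmM = lp + logI[w, i_arr[:, None], iw] + logI[z, iw, j_arr[:, None]]
                    avM = None
                    if with_A:
                        avM = lp + A[w, i_arr[:, None], iw] + A[z, iw, j_arr[:, None]]
                    tot, a = _wlogsum(lmM, avM, axis=1)
                    lms.append(tot)
                    if with_A:
                        avs.append(a)
            for _, w, leff, aconst, _lmax, _r, _side in c.effs_of[v]:
                lms.append(dtype(leff) + logI[w, i_arr, j_arr])
                if with_A:
                    avs.append(dtype(aconst) + A[w, i_arr, j_arr])
            if not lms:
                continue
            tot, a = _wlogsum(np.stack(lms), np.stack(avs) if with_A else None, axis=0)
            logI[v, i_arr, j_arr] = tot
            if with_A:
                A[v, i_arr, j_arr] = a
    return logI, A


def inside_logZ(g: Grammar, seq: str, dtype=np.float64) -> float:
    """Natural log of the total probability of all derivations of ``seq``."""
    seq_idx = encode_sequence(seq)
    if len(seq_idx) == 0:
        c = g.compiled
        s0 = c.idx[g.start]
        if c.eps_logmass[s0] > _NEG_INF:
            return float(c.eps_logmass[s0])
        raise ValueError("empty sequence and grammar has no epsilon start derivation")
    logI, _ = _inside(g, seq_idx, dtype=dtype)
    lz = float(logI[g.compiled.idx[g.start], 0, len(seq_idx)])
    if lz == _NEG_INF:
        raise ZeroProbabilityError(f"sequence not derivable under grammar {g!r}")
    return lz


def derivation_entropy(g: Grammar, seq: str, base: float | None = None, dtype=np.float64) -> float:
    """Exact Shannon entropy (nats) of the derivation distribution given ``seq``.

    H = ln Z − E[ln P(π) | seq].  Equals the folding-space structure entropy
    when the grammar is structurally unambiguous.  ``base`` converts the
    result (e.g. ``base=2`` for bits); default natural log.
    """
    seq_idx = encode_sequence(seq)
    if len(seq_idx) == 0:
        raise ValueError("empty sequence")
    logI, A = _inside(g, seq_idx, with_A=True, dtype=dtype)
    s0 = g.compiled.idx[g.start]
    n = len(seq_idx)
    lz = float(logI[s0, 0, n])
    if lz == _NEG_INF:
        raise ZeroProbabilityError("sequence not derivable under grammar")
    h = lz - float(A[s0, 0, n])
    if h < -1e-6:
        raise ArithmeticError(f"entropy computed negative ({h}); numerical failure")
    h = max(h, 0.0)
    if base is not None:
        h /= math.log(base)
    return h


# ---------------------------------------------------------------------------
# Outside DP and pair probabilities


def _outside(g: Grammar, seq_idx: np.ndarray, logI: np.ndarray) -> np.ndarray:
    c = g.compiled
    n = len(seq_idx)
    K = c.K
    logO = np.full((K, n + 1, n + 1), _NEG_INF)
    logO[c.idx[g.start], 0, n] = 0.0
    min_hp = g.min_hairpin
    rev_topo = list(reversed(c.topo))  # parents before children on same span
    for L in range(n, 0, -1):
        i_arr = np.arange(0, n - L + 1)
        j_arr = i_arr + L
        for v in rev_topo:
            O_v = logO[v, i_arr, j_arr]
            if not np.isfinite(O_v).any():
                continue
            for _, w, leff, _ac, _lm, _r, _side in c.effs_of[v]:
                tgt = logO[w, i_arr, j_arr]
                logO[w, i_arr, j_arr] = np.logaddexp(tgt, O_v + leff)
            if L - 2 >= 1 and L - 2 >= min_hp:
                for _, w, mat in c.pairs_of[v]:
                    plog = mat[seq_idx[i_arr], seq_idx[j_arr - 1]]
                    contrib = O_v + plog
                    tgt = logO[w, i_arr + 1, j_arr - 1]
                    logO[w, i_arr + 1, j_arr - 1] = np.logaddexp(tgt, contrib)
            if L >= 2:
                for _, w, z, lp, _r in c.binaries_of[v]:
                    for m in range(1, L):
                        mid = i_arr + m
                        cw = O_v + lp + logI[z, mid, j_arr]
                        tgt = logO[w, i_arr, mid]
                        logO[w, i_arr, mid] = np.logaddexp(tgt, cw)
                        cz = O_v + lp + logI[w, i_arr, mid]
                        tgt = logO[z, mid, j_arr]
                        logO[z, mid, j_arr] = np.logaddexp(tgt, cz)
    return logO


def pair_probabilities(g: Grammar, seq: str) -> np.ndarray:
    """Posterior pairing matrix: P[i, j] (0-based, i<j) that i pairs with j.

    Computed by inside–outside over the pair-emission rules; stored
    upper-triangular (zeros elsewhere).
    """
    seq_idx = encode_sequence(seq)
    n = len(seq_idx)
    if n == 0:
        raise ValueError("empty sequence")
    c = g.compiled
    logI, _ = _inside(g, seq_idx)
    lz = float(logI[c.idx[g.start], 0, n])
    if lz == _NEG_INF:
        raise ZeroProbabilityError("sequence not derivable under grammar")
    logO = _outside(g, seq_idx, logI)
    P = np.zeros((n, n))
    min_hp = g.min_hairpin
    for L in range(2 + min_hp, n + 1):
        i_arr = np.arange(0, n - L + 1)
        j_arr = i_arr + L
        acc = np.full(len(i_arr), _NEG_INF)
        for v, w, mat in c.pair_groups:
            plog = mat[seq_idx[i_arr], seq_idx[j_arr - 1]]
            if L == 2:
                inner = c.eps_logmass[w]
            else:
                inner = logI[w, i_arr + 1, j_arr - 1]
            acc = np.logaddexp(acc, logO[v, i_arr, j_arr] + plog + inner)
        vals = np.exp(acc - lz)
        P[i_arr, j_arr - 1] = np.clip(vals, 0.0, 1.0)
    return P


# ---------------------------------------------------------------------------
# CYK (max) DP with deterministic tie-breaking


def _cyk_chart(g: Grammar, seq_idx: np.ndarray, mask: _Mask | None = None):
    """Max-probability chart with backpointers.

    Ties are broken deterministically: the first contribution in grammar
    rule order wins, and for binary splits the leftmost split point wins
    (numpy argmax keeps the first occurrence).
    """
    c = g.compiled
    n = len(seq_idx)
    K = c.K
    best = np.full((K, n + 1, n + 1), _NEG_INF)
    choice = np.full((K, n + 1, n + 1), -1, dtype=np.int32)
    split = np.zeros((K, n + 1, n + 1), dtype=np.int32)
    min_hp = g.min_hairpin
    # contribution descriptors per nonterminal, in tie-break order
    descr: list[list[tuple]] = [[] for _ in range(K)]
    for v in range(K):
        descr[v].append(("emit",))
        for gi, (vv, w, mat) in enumerate(c.pair_groups):
            if vv == v:
                descr[v].append(("pair", gi, w))
        for b in c.binaries_of[v]:
            descr[v].append(("binary", b))
        for e in c.effs_of[v]:
            descr[v].append(("eff", e))

    for L in range(1, n + 1):
        i_arr = np.arange(0, n - L + 1)
        j_arr = i_arr + L
        for v in c.topo:
            vals: list[np.ndarray] = []
            msel: list[np.ndarray | None] = []
            for d in descr[v]:
                if d[0] == "emit":
                    if L == 1:
                        lm = c.emit_logp[v, seq_idx[i_arr]].copy()
                        if mask is not None:
                            lm = np.where(mask.unpaired_ok[i_arr], lm, _NEG_INF)
                    else:
                        lm = np.full(len(i_arr), _NEG_INF)
                    vals.append(lm)
                    msel.append(None)
                elif d[0] == "pair":
                    _, gi, w = d
                    mat = c.pair_groups[gi][2]
                    if L >= 2 and L - 2 >= min_hp:
                        plog = mat[seq_idx[i_arr], seq_idx[j_arr - 1]]
                        if mask is not None:
                            plog = np.where(mask.pair_ok[i_arr, j_arr - 1], plog, _NEG_INF)
                        inner = c.eps_logmax[w] if L == 2 else best[w, i_arr + 1, j_arr - 1]
                        vals.append(plog + inner)
                    else:
                        vals.append(np.full(len(i_arr), _NEG_INF))
                    msel.append(None)
                elif d[0] == "binary":
                    _, (_, w, z, lp, _r) = d
                    if L >= 2:
                        m_arr = np.arange(1, L)
                        iw = i_arr[:, None] + m_arr[None, :]
                        M = lp + best[w, i_arr[:, None], iw] + best[z, iw, j_arr[:, None]]
                        bm = np.argmax(M, axis=1)
                        vals.append(M[np.arange(len(i_arr)), bm])
                        msel.append(bm + 1)
                    else:
                        vals.append(np.full(len(i_arr), _NEG_INF))
                        msel.append(None)
                else:  # eff unit
                    _, (_, w, _leff, _ac, lmax, _r, _side) = d
                    vals.append(lmax + best[w, i_arr, j_arr])
                    msel.append(None)
            V = np.stack(vals)
            ci = np.argmax(V, axis=0)
            bv = V[ci, np.arange(len(i_arr))]
            best[v, i_arr, j_arr] = bv
            choice[v, i_arr, j_arr] = np.where(np.isfinite(bv), ci, -1)
            for k, bm in enumerate(msel):
                if bm is not None:
                    sel = ci == k
                    if sel.any():
                        split[v, i_arr[sel], j_arr[sel]] = bm[sel]
    return best, choice, split, descr


def _cyk_backtrack(
    g: Grammar,
    n: int,
    choice: np.ndarray,
    split: np.ndarray,
    descr: list[list[tuple]],
    collect_rules: bool = False,
    seq_idx: np.ndarray | None = None,
):
    c = g.compiled
    pairs: list[tuple[int, int]] = []
    uses: list[Rule] = []
    stack = [(c.idx[g.start], 0, n)]
    while stack:
        v, i, j = stack.pop()
        d = descr[v][choice[v, i, j]]
        if d[0] == "emit":
            if collect_rules:
                uses.append(c.emit_rule[(v, int(seq_idx[i]))])
        elif d[0] == "pair":
            _, gi, w = d
            pairs.append((i + 1, j))
            if collect_rules:
                x, y = int(seq_idx[i]), int(seq_idx[j - 1])
                uses.append(c.pair_rule[(v, w, x, y)])
            if j - i > 2:
                stack.append((w, i + 1, j - 1))
        elif d[0] == "binary":
            _, (_, w, z, _lp, r) = d
            m = int(split[v, i, j])
            if collect_rules:
                uses.append(r)
            stack.append((w, i, i + m))
            stack.append((z, i + m, j))
        else:
            _, (_, w, _leff, _ac, _lm, r, _side) = d
            if collect_rules:
                uses.append(r)
            stack.append((w, i, j))
    return pairs, uses


def cyk_predict(g: Grammar, seq: str, return_logp: bool = False):
    """Structure of a maximum-probability derivation of ``seq``.

    Deterministic: ties prefer the first rule in grammar order and the
    leftmost binary split.
    """
    seq_idx = encode_sequence(seq)
    n = len(seq_idx)
    if n == 0:
        raise ValueError("empty sequence")
    best, choice, split, descr = _cyk_chart(g, seq_idx)
    s0 = g.compiled.idx[g.start]
    lp = float(best[s0, 0, n])
    if lp == _NEG_INF:
        raise ZeroProbabilityError("sequence not derivable under grammar")
    pairs, _ = _cyk_backtrack(g, n, choice, split, descr)
    ss = SecondaryStructure.from_pairs(n, pairs)
    return (ss, lp) if return_logp else ss


# ---------------------------------------------------------------------------
# Conditional sampling (stochastic traceback)


def sample_structures_scfg(
    g: Grammar, seq: str, k: int, rng: np.random.Generator
) -> list[SecondaryStructure]:
    """Draw ``k`` structures from the sequence-conditioned SCFG distribution.

    Stochastic traceback of the inside chart: at each cell a contribution
    (and split point) is drawn proportional to its inside mass, so samples
    are exact draws from P(derivation | sequence).
    """
    if k <= 0:
        raise ValueError("sample count must be positive")
    seq_idx = encode_sequence(seq)
    n = len(seq_idx)
    c = g.compiled
    logI, _ = _inside(g, seq_idx)
    s0 = c.idx[g.start]
    if logI[s0, 0, n] == _NEG_INF:
        raise ZeroProbabilityError("sequence not derivable under grammar")
    min_hp = g.min_hairpin

    def cell_contribs(v: int, i: int, j: int):
        """Yield (logmass, action) for every contribution to cell (v,i,j)."""
        L = j - i
        out = []
        if L == 1:
            lm = c.emit_logp[v, seq_idx[i]]
            if np.isfinite(lm):
                out.append((lm, ("emit",)))
        if L >= 2 and L - 2 >= min_hp:
            for _, w, mat in c.pairs_of[v]:
                plog = mat[seq_idx[i], seq_idx[j - 1]]
                if not np.isfinite(plog):
                    continue
                inner = c.eps_logmass[w] if L == 2 else logI[w, i + 1, j - 1]
                if np.isfinite(inner):
                    out.append((plog + inner, ("pair", w)))
        if L >= 2:
            for _, w, z, lp, _r in c.binaries_of[v]:
                for m in range(1, L):
                    lm = lp + logI[w, i, i + m] + logI[z, i + m, j]
                    if np.isfinite(lm):
                        out.append((lm, ("binary", w, z, m)))
        for _, w, leff, _ac, _lm, _r, _side in c.effs_of[v]:
            lm = leff + logI[w, i, j]
            if np.isfinite(lm):
                out.append((lm, ("eff", w)))
        return out

    samples = []
    for _ in range(k):
        pairs: list[tuple[int, int]] = []
        stack = [(s0, 0, n)]
        while stack:
            v, i, j = stack.pop()
            contribs = cell_contribs(v, i, j)
            lms = np.array([lm for lm, _ in contribs])
            p = np.exp(lms - lms.max())
            p /= p.sum()
            a = contribs[int(rng.choice(len(contribs), p=p))][1]
            if a[0] == "pair":
                pairs.append((i + 1, j))
                if j - i > 2:
                    stack.append((a[1], i + 1, j - 1))
            elif a[0] == "binary":
                _, w, z, m = a
                stack.append((w, i, i + m))
                stack.append((z, i + m, j))
            elif a[0] == "eff":
                stack.append((a[1], i, j))
        samples.append(SecondaryStructure.from_pairs(n, pairs))
    return samples


def sample_from_grammar(
    g: Grammar, rng: np.random.Generator, max_len: int = 200, max_tries: int = 1000
) -> tuple[str, SecondaryStructure]:
    """Generate one (sequence, structure) pair from the grammar's own
    distribution (unconditional ancestral sampling; draws longer than
    ``max_len`` are rejected and redrawn)."""
    rules_of: dict[str, list[Rule]] = {}
    for r in g.rules:
        rules_of.setdefault(r.lhs, []).append(r)
    probs_of = {v: np.array([r.prob for r in rs]) for v, rs in rules_of.items()}

    for _ in range(max_tries):
        chars: list[str] = []
        pairs: list[tuple[int, int]] = []
        ok = True
        stack: list[str] = [g.start]
        # expand leftmost-first; pair emissions record (open, placeholder)
        def expand(v: str) -> bool:
            if len(chars) > max_len:
                return False
            rs = rules_of[v]
            r = rs[int(rng.choice(len(rs), p=probs_of[v] / probs_of[v].sum()))]
            if r.kind == "emit":
                chars.append(r.terminal)
            elif r.kind == "pair":
                open_pos = len(chars)
                chars.append(r.left)
                if not expand(r.child):
                    return False
                chars.append(r.right)
                pairs.append((open_pos + 1, len(chars)))
            elif r.kind == "binary":
                if not expand(r.children[0]):
                    return False
                if not expand(r.children[1]):
                    return False
            elif r.kind == "unit":
                return expand(r.child)
            return len(chars) <= max_len
        try:
            ok = expand(g.start)
        except RecursionError:
            ok = False
        if ok and chars:
            return "".join(chars), SecondaryStructure.from_pairs(len(chars), pairs)
    raise RuntimeError(f"could not sample a sequence of length <= {max_len}")


# ---------------------------------------------------------------------------
# Counting maximum-likelihood training


def estimate_parameters(
    training: Sequence[tuple[str, SecondaryStructure]],
    grammar_shape: Grammar,
    pseudocount: float = 0.0,
) -> Grammar:
    """Counting MLE: rule probabilities from relative rule-use frequencies.

    Each training structure must be derivable under the shape; for
    structure-unambiguous shapes (the intended use) the structure-faithful
    derivation is unique and its rule uses are counted exactly.  Grammars
    with ε-deriving nonterminals are rejected for training.
    """
    if not training:
        raise ValueError("empty training set")
    c = grammar_shape.compiled
    if c.has_epsilon:
        raise GrammarError("training requires a grammar without epsilon derivations")
    counts: dict[Rule, float] = {r: 0.0 for r in grammar_shape.rules}
    for rec_no, (seq, struct) in enumerate(training):
        seq_idx = encode_sequence(seq)
        n = len(seq_idx)
        mask = _Mask.from_structure(n, struct)
        best, choice, split, descr = _cyk_chart(grammar_shape, seq_idx, mask=mask)
        if best[c.idx[grammar_shape.start], 0, n] == _NEG_INF:
            raise ValueError(
                f"training record {rec_no}: structure not derivable under grammar shape"
            )
        _, uses = _cyk_backtrack(
            grammar_shape, n, choice, split, descr, collect_rules=True, seq_idx=seq_idx
        )
        for r in uses:
            counts[r] += 1.0
    new_rules = []
    lhs_tot: dict[str, float] = {}
    for r in grammar_shape.rules:
        lhs_tot[r.lhs] = lhs_tot.get(r.lhs, 0.0) + counts[r] + pseudocount
    for r in grammar_shape.rules:
        tot = lhs_tot[r.lhs]
        if tot > 0:
            p = (counts[r] + pseudocount) / tot
        else:
            p = r.prob  # unseen nonterminal keeps its shape probability
        new_rules.append(
            Rule(r.lhs, r.kind, p, terminal=r.terminal, left=r.left,
                 right=r.right, child=r.child, children=r.children)
        )
    return Grammar(
        new_rules,
        start=grammar_shape.start,
        allowed_pairs=grammar_shape.allowed_pairs,
        min_hairpin=grammar_shape.min_hairpin,
    )


@dataclass
class ParseResult:
    """Bundle of the per-sequence grammar statistics."""

    log_inside: float
    entropy_nats: float
    pair_prob: np.ndarray = field(repr=False)


def parse_sequence(g: Grammar, seq: str) -> ParseResult:
    """Convenience: logZ, entropy, and pairing matrix in one call."""
    return ParseResult(
        log_inside=inside_logZ(g, seq),
        entropy_nats=derivation_entropy(g, seq),
        pair_prob=pair_probabilities(g, seq),
    )
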