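"""Substitution models, corrected pairwise distances, tree likelihoods
and AIC-based model choice.

The model family is the GTR hierarchy restricted to the candidates used
for barcode data: JC, K2P, HKY, TrN and GTR, each with or without a
proportion of invariant sites (+I).  Distances are maximum-likelihood
"corrected p-distances": for JC and K2P the classical closed forms, for
the richer models a one-dimensional likelihood optimisation over the
pairwise divergence time with the model parameters held fixed (the model
is estimated once per locus, not re-fitted per pair).

Conventions
-----------
* Rate matrices are normalised to one expected substitution per unit
  time among variable sites; under +I a reported distance is the
  expected number of substitutions per site averaged over all sites,
  i.e. ``(1 - p_inv) * t``.
* Pairwise distances use pairwise deletion: a site contributes only if
  both sequences carry an unambiguous base there.
* Likelihood computations (pruning) keep gaps and ambiguity codes as
  partial-state vectors (a gap is compatible with every base).
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _iupac
from .errors import (AlignmentError, EsudelimError, LabelMismatchError,
                     SaturationError, UndefinedDistanceError)
from .matrices import DIAG_ZERO, LabelledMatrix
from .partition import UnitPartition
from .trees import SupportTree

FAMILIES = ("JC", "K2P", "HKY", "TrN", "GTR")

# free parameters per family: exchangeabilities + base frequencies
_FREE_PARAMS = {"JC": 0, "K2P": 1, "HKY": 1 + 3, "TrN": 2 + 3, "GTR": 5 + 3}

_UNIFORM_PI = (0.25, 0.25, 0.25, 0.25)


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length IUPAC DNA sequences for one locus."""

    labels: list[str]
    sequences: list[str]
    locus: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise AlignmentError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError("duplicate sequence labels")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences of unequal length: {sorted(lengths)}")
        self._masks: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def masks(self) -> np.ndarray:
        """(n, length) uint8 IUPAC bitmask matrix."""
        if self._masks is None:
            self._masks = np.vstack([_iupac.encode(s) for s in self.sequences]) \
                if self.sequences else np.zeros((0, 0), np.uint8)
        return self._masks

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    def subset(self, labels: list[str]) -> "Alignment":
        return Alignment(list(labels),
                         [self.sequence(l) for l in labels], self.locus)

    def take_sites(self, idx: np.ndarray) -> "Alignment":
        """New alignment keeping site columns ``idx`` (with repetition)."""
        arr = np.array([list(s) for s in self.sequences])
        return Alignment(list(self.labels),
                         ["".join(row) for row in arr[:, idx]], self.locus)

    def concatenate(self, other: "Alignment", locus: str = "") -> "Alignment":
        if self.labels != other.labels:
            raise LabelMismatchError("concatenation requires identical labels")
        return Alignment(list(self.labels),
                         [a + b for a, b in zip(self.sequences,
                                                other.sequences)],
                         locus or f"{self.locus}+{other.locus}")


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible nucleotide model of the GTR+I hierarchy.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT,
    GT with the GTR normalisation rate(GT) = 1; ``pi`` are the base
    frequencies (A, C, G, T); ``p_inv`` the proportion of invariant
    sites.
    """

    family: str
    pi: tuple[float, float, float, float] = _UNIFORM_PI
    rates: tuple[float, ...] = (1.0,) * 6
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise EsudelimError(f"unknown model family {self.family!r}")
        pi = np.asarray(self.pi, float)
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise EsudelimError("base frequencies must be >0 and sum to 1")
        r = np.asarray(self.rates, float)
        if r.shape != (6,) or (r <= 0).any():
            raise EsudelimError("need 6 positive exchangeabilities")
        if not (0.0 <= self.p_inv < 1.0):
            raise EsudelimError("p_inv must be in [0, 1)")

    # -- constructors ---------------------------------------------------
    @classmethod
    def jc(cls, p_inv: float = 0.0) -> "SubstitutionModel":
        return cls("JC", p_inv=p_inv)

    @classmethod
    def k2p(cls, kappa: float = 2.0, p_inv: float = 0.0) -> "SubstitutionModel":
        return cls("K2P", rates=(1, kappa, 1, 1, kappa, 1), p_inv=p_inv)

    @classmethod
    def hky(cls, kappa: float, pi, p_inv: float = 0.0) -> "SubstitutionModel":
        return cls("HKY", tuple(pi), (1, kappa, 1, 1, kappa, 1), p_inv)

    @classmethod
    def trn(cls, kappa_ag: float, kappa_ct: float, pi,
            p_inv: float = 0.0) -> "SubstitutionModel":
        return cls("TrN", tuple(pi), (1, kappa_ag, 1, 1, kappa_ct, 1), p_inv)

    @classmethod
    def gtr(cls, rates, pi, p_inv: float = 0.0) -> "SubstitutionModel":
        r = np.asarray(rates, float)
        r = r / r[5]  # GTR normalisation r_GT = 1
        return cls("GTR", tuple(pi), tuple(r), p_inv)

    # -- derived quantities ---------------------------------------------
    @property
    def n_free_params(self) -> int:
        """Free exchangeabilities + frequencies (+1 for p_inv if > 0)."""
        return _FREE_PARAMS[self.family] + (1 if self.p_inv > 0 else 0)

    def rate_matrix(self) -> np.ndarray:
        """Q normalised to one expected substitution per unit time."""
        pi = np.asarray(self.pi, float)
        r = np.asarray(self.rates, float)
        q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), rij in zip(pairs, r):
            q[i, j] = rij * pi[j]
            q[j, i] = rij * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the reversible eigendecomposition."""
        sqrt_pi, inv_sqrt_pi, w, u = _eigen(self)
        e = np.exp(w * t)
        p = (inv_sqrt_pi[:, None] * u) @ (e[:, None] * u.T) * sqrt_pi[None, :]
        return np.clip(p, 0.0, None)


@functools.lru_cache(maxsize=256)
def _eigen(model: SubstitutionModel):
    pi = np.asarray(model.pi, float)
    q = model.rate_matrix()
    sqrt_pi = np.sqrt(pi)
    b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
    w, u = np.linalg.eigh((b + b.T) / 2.0)
    return sqrt_pi, 1.0 / sqrt_pi, w, u


# ---------------------------------------------------------------------------
# alignment statistics & haplotypes
# ---------------------------------------------------------------------------

@dataclass
class AlignmentStats:
    length: int
    n_variable: int
    n_parsimony_informative: int
    tstv_observed: float  # NaN when no transversions observed

    def __post_init__(self) -> None:
        if not (self.n_parsimony_informative <= self.n_variable
                <= self.length):
            raise EsudelimError("inconsistent site counts")


def alignment_stats(aln: Alignment) -> AlignmentStats:
    """Variable / parsimony-informative site counts and observed ts/tv.

    A site is parsimony informative when at least two distinct
    unambiguous bases are each carried by at least two sequences; gaps
    and ambiguity codes never count as states.  The ts/tv ratio pools
    transition and transversion counts over all unordered sequence pairs
    (pairwise deletion per pair).
    """
    if aln.n == 0:
        raise AlignmentError("empty alignment")
    idx = _iupac.base_index(aln.masks)  # (n, L), -1 = not a plain base
    counts = np.stack([(idx == b).sum(axis=0) for b in range(4)])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_variable = int((n_states >= 2).sum())
    n_pi = int(((counts >= 2).sum(axis=0) >= 2).sum())

    is_purine = (idx == 0) | (idx == 2)
    valid = idx >= 0
    ts = tv = 0
    for i, j in itertools.combinations(range(aln.n), 2):
        both = valid[i] & valid[j]
        diff = both & (idx[i] != idx[j])
        same_class = is_purine[i] == is_purine[j]
        ts += int((diff & same_class).sum())
        tv += int((diff & ~same_class).sum())
    ratio = ts / tv if tv else float("nan")
    return AlignmentStats(aln.length, n_variable, n_pi, ratio)


def collapse_haplotypes(aln: Alignment, prefix: str = "Hap"
                        ) -> tuple[UnitPartition, Alignment]:
    """Group specimens with literally identical (uppercased) sequences.

    Returns the specimen->haplotype partition and a representative
    alignment (first-seen representative per haplotype, input order).
    """
    seen: dict[str, str] = {}
    assignment: dict[str, str] = {}
    rep_labels: list[str] = []
    rep_seqs: list[str] = []
    for label, seq in zip(aln.labels, aln.sequences):
        if seq not in seen:
            name = f"{prefix}{len(seen) + 1}"
            seen[seq] = name
            rep_labels.append(name)
            rep_seqs.append(seq)
        assignment[label] = seen[seq]
    part = UnitPartition(assignment, rep_labels)
    return part, Alignment(rep_labels, rep_seqs, aln.locus)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceRecord:
    p: float                 # uncorrected mismatch proportion
    n_compared: int          # sites with unambiguous bases in both
    d: float | None = None   # model-corrected distance

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise EsudelimError("p outside [0, 1]")


def _pair_masks(a, b) -> tuple[np.ndarray, np.ndarray]:
    ma = _iupac.encode(a.upper()) if isinstance(a, str) else np.asarray(a)
    mb = _iupac.encode(b.upper()) if isinstance(b, str) else np.asarray(b)
    if ma.shape != mb.shape:
        raise AlignmentError("sequences of unequal length")
    return ma, mb


def p_distance(a, b) -> DistanceRecord:
    """Uncorrected distance under pairwise deletion of gaps/ambiguities."""
    ma, mb = _pair_masks(a, b)
    valid = _iupac.is_unambiguous(ma) & _iupac.is_unambiguous(mb)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedDistanceError("no unambiguous sites shared by pair")
    mismatches = int((ma[valid] != mb[valid]).sum())
    return DistanceRecord(p=mismatches / n, n_compared=n)


def _pair_counts(ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
    """4x4 site-count table over unambiguous shared sites."""
    ia, ib = _iupac.base_index(ma), _iupac.base_index(mb)
    valid = (ia >= 0) & (ib >= 0)
    return np.bincount((ia[valid] * 4 + ib[valid]).astype(int),
                       minlength=16).reshape(4, 4).astype(float)


def jc_correct(p: float) -> float:
    """Jukes-Cantor closed form d = -(3/4) ln(1 - 4p/3)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"p = {p:.4f} at or beyond JC saturation (3/4)")
    return -0.75 * np.log(arg)


def k2p_correct(p_ts: float, p_tv: float) -> float:
    """Kimura two-parameter closed form from transition/transversion
    proportions."""
    w1 = 1.0 - 2.0 * p_ts - p_tv
    w2 = 1.0 - 2.0 * p_tv
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"P = {p_ts:.4f}, Q = {p_tv:.4f} beyond K2P saturation")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


_T_MAX = 10.0
_T_TOL = 1e-8


def corrected_distance(a, b, model: SubstitutionModel) -> DistanceRecord:
    """Model-corrected pairwise distance.

    JC and K2P (without invariant sites) use their closed forms.  All
    other models maximise the pairwise likelihood over the divergence
    time t in [0, 10] with the model held fixed; with invariant sites
    the per-site likelihood is the mixture
    ``p_inv * pi_x * [x == y] + (1 - p_inv) * pi_x * P_xy(t)``
    and the reported distance is ``(1 - p_inv) * t``.
    """
    ma, mb = _pair_masks(a, b)
    rec = p_distance(ma, mb)
    if rec.p == 0.0:
        rec.d = 0.0
        return rec

    counts = _pair_counts(ma, mb)
    if model.family == "JC" and model.p_inv == 0.0:
        rec.d = jc_correct(rec.p)
        return rec
    if model.family == "K2P" and model.p_inv == 0.0:
        n = counts.sum()
        p_ts = (counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]) / n
        p_tv = rec.p - p_ts
        rec.d = k2p_correct(p_ts, p_tv)
        return rec

    pi = np.asarray(model.pi, float)
    p_inv = model.p_inv
    ident = np.diag(pi)

    def nll(t: float) -> float:
        site_lik = (1.0 - p_inv) * pi[:, None] \
            * model.transition_probabilities(t)
        if p_inv:
            site_lik = site_lik + p_inv * ident
        with np.errstate(divide="ignore"):
            lg = np.log(site_lik)
        lg[counts == 0] = 0.0  # avoid -inf * 0
        if np.isneginf(lg[counts > 0]).any():
            return np.inf
        return -(counts * lg).sum()

    res = optimize.minimize_scalar(nll, bounds=(0.0, _T_MAX),
                                   method="bounded",
                                   options={"xatol": _T_TOL})
    t_opt = float(res.x)
    if t_opt >= _T_MAX - 1e-3:
        raise SaturationError(
            "pairwise likelihood optimum at the divergence bound; "
            "pair is saturated under the model")
    rec.d = (1.0 - p_inv) * t_opt
    return rec


def distance_matrix(aln: Alignment, model: SubstitutionModel,
                    units: UnitPartition | None = None, intra: str = "max"):
    """Specimen-level corrected distance matrix.

    With ``units`` given, also returns the unit-level summary matrix
    (between-unit minimum off the diagonal, within-unit aggregate on it;
    singletons get a missing diagonal).
    """
    n = aln.n
    vals = np.zeros((n, n))
    masks = aln.masks
    for i in range(n):
        for j in range(i + 1, n):
            rec = corrected_distance(masks[i], masks[j], model)
            vals[i, j] = vals[j, i] = rec.d
    dm = LabelledMatrix(list(aln.labels), vals, DIAG_ZERO)
    if units is None:
        return dm
    from .delineation import unit_summary
    return dm, unit_summary(dm, units, intra=intra)


# ---------------------------------------------------------------------------
# tree likelihood (Felsenstein pruning) and model selection
# ---------------------------------------------------------------------------

def _site_patterns(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    cols = aln.masks.T  # (L, n)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def tree_log_likelihood(aln: Alignment, tree: SupportTree,
                        model: SubstitutionModel) -> float:
    """Log-likelihood of ``aln`` on ``tree`` under ``model``.

    Felsenstein pruning over compressed site patterns; gaps and
    ambiguity codes enter as partial-state vectors (gap = all ones).
    Branch lengths are expected substitutions per site averaged over all
    sites, so with invariant sites the variable class evolves for
    ``t / (1 - p_inv)``.
    """
    tree.require_leaves(aln.labels)
    patterns, counts = _site_patterns(aln)
    npat = patterns.shape[0]
    label_row = {lab: k for k, lab in enumerate(aln.labels)}
    pi = np.asarray(model.pi, float)
    p_inv = model.p_inv
    scale = 1.0 / (1.0 - p_inv)

    bit = np.array([_iupac.A, _iupac.C, _iupac.G, _iupac.T], np.uint8)

    def leaf_partial(lab: str) -> np.ndarray:
        m = patterns[:, label_row[lab]]
        return ((m[:, None] & bit[None, :]) > 0).astype(float)

    log_scaler = np.zeros(npat)

    def prune(node) -> np.ndarray:
        nonlocal log_scaler
        if node.is_leaf():
            part = leaf_partial(node.taxon.label)
        else:
            part = np.ones((npat, 4))
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * scale
                p = model.transition_probabilities(t)
                part = part * (prune(child) @ p.T)
            mx = part.max(axis=1)
            nz = mx > 0
            part[nz] = part[nz] / mx[nz, None]
            with np.errstate(divide="ignore"):
                log_scaler += np.where(nz, np.log(mx, where=nz,
                                                  out=np.zeros_like(mx)), 0.0)
        return part

    root = tree.tree.seed_node
    root_partial = prune(root)
    lik_var = root_partial @ pi
    if p_inv:
        inter = np.bitwise_and.reduce(patterns, axis=1)
        lik_inv = ((inter[:, None] & bit[None, :]) > 0).astype(float) @ pi
        site_lik = p_inv * lik_inv + (1.0 - p_inv) * lik_var * np.exp(log_scaler)
        # note: invariant component must not carry the pruning scaler
        with np.errstate(divide="ignore"):
            return float((counts * np.log(site_lik)).sum())
    with np.errstate(divide="ignore"):
        return float((counts * (np.log(lik_var) + log_scaler)).sum())


def empirical_base_frequencies(aln: Alignment) -> tuple[float, ...]:
    idx = _iupac.base_index(aln.masks)
    counts = np.array([(idx == b).sum() for b in range(4)], float) + 1.0
    return tuple(counts / counts.sum())


@dataclass
class ModelFit:
    model: SubstitutionModel
    lnL: float
    k: int
    converged: bool = True
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = 2.0 * self.k - 2.0 * self.lnL


def _build_model(family: str, pi, theta: np.ndarray, p_inv: float
                 ) -> SubstitutionModel:
    if family == "JC":
        return SubstitutionModel("JC", p_inv=p_inv)
    if family == "K2P":
        return SubstitutionModel.k2p(theta[0], p_inv)
    if family == "HKY":
        return SubstitutionModel.hky(theta[0], pi, p_inv)
    if family == "TrN":
        return SubstitutionModel.trn(theta[0], theta[1], pi, p_inv)
    rates = np.append(theta[:5], 1.0)
    return SubstitutionModel("GTR", tuple(pi), tuple(rates), p_inv)


_N_THETA = {"JC": 0, "K2P": 1, "HKY": 1, "TrN": 2, "GTR": 5}
_MAXITER = 500


def select_model_aic(aln: Alignment, topology: SupportTree | None = None,
                     families=FAMILIES, try_inv: bool = True
                     ) -> tuple[ModelFit, list[ModelFit]]:
    """Choose the best-fitting model by AIC on a fixed topology.

    Candidates are {JC, K2P, HKY, TrN, GTR} x {+I, without I}.  Per
    candidate, exchangeabilities, p_inv and all branch lengths are
    optimised jointly (L-BFGS-B, capped at 500 iterations; a
    non-converged fit is flagged and excluded from "best"); base
    frequencies are the empirical counts.  AIC = 2k - 2 lnL with k the
    free exchangeabilities + frequencies + p_inv.  Ties within the
    numerical tolerance break toward fewer parameters.
    """
    if topology is None:
        topology = _nj_topology(aln)
    topology.require_leaves(aln.labels)
    pi_emp = empirical_base_frequencies(aln)
    edges = [e for e in topology.tree.preorder_edge_iter()
             if e.head_node is not topology.tree.seed_node]
    bl0 = np.array([max(e.length or 0.0, 1e-6) for e in edges])

    def set_branches(x: np.ndarray) -> None:
        for e, v in zip(edges, x):
            e.length = float(v)

    fits: list[ModelFit] = []
    inv_options = (False, True) if try_inv else (False,)
    for family in families:
        for with_inv in inv_options:
            n_theta = _N_THETA[family]
            x0 = np.concatenate([np.full(n_theta, 2.0 if n_theta <= 2 else 1.0),
                                 [0.2] if with_inv else [],
                                 bl0])
            bounds = ([(1e-3, 200.0)] * n_theta
                      + ([(0.0, 0.95)] if with_inv else [])
                      + [(0.0, 20.0)] * len(edges))

            def nll(x, family=family, with_inv=with_inv, n_theta=n_theta):
                theta = x[:n_theta]
                p_inv = x[n_theta] if with_inv else 0.0
                set_branches(x[n_theta + int(with_inv):])
                try:
                    m = _build_model(family, pi_emp, theta, p_inv)
                except EsudelimError:
                    return np.inf
                ll = tree_log_likelihood(aln, topology, m)
                return np.inf if not np.isfinite(ll) else -ll

            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": _MAXITER})
            theta = res.x[:n_theta]
            p_inv = float(res.x[n_theta]) if with_inv else 0.0
            model = _build_model(family, pi_emp, theta, min(p_inv, 0.949))
            k = _FREE_PARAMS[family] + int(with_inv)
            fits.append(ModelFit(model, -float(res.fun), k,
                                 converged=bool(res.success)
                                 or res.nit < _MAXITER))
    set_branches(bl0)
    ok = [f for f in fits if f.converged] or fits
    best_aic = min(f.aic for f in ok)
    best = min((f for f in ok if f.aic <= best_aic + 1e-6),
               key=lambda f: f.k)
    return best, fits


def _nj_topology(aln: Alignment) -> SupportTree:
    """NJ guide tree from JC distances (p-distance fallback on saturation)."""
    from .treetools import nj_tree
    n = aln.n
    vals = np.zeros((n, n))
    masks = aln.masks
    for i in range(n):
        for j in range(i + 1, n):
            rec = p_distance(masks[i], masks[j])
            try:
                d = jc_correct(rec.p) if rec.p > 0 else 0.0
            except SaturationError:
                d = rec.p
            vals[i, j] = vals[j, i] = d
    return nj_tree(LabelledMatrix(list(aln.labels), vals, DIAG_ZERO))


# ---------------------------------------------------------------------------
# reading-frame sanity check
# ---------------------------------------------------------------------------

def frame_stop_counts(aln: Alignment, table: int = 4) -> dict[int, int]:
    """Stop codons per reading frame (0, 1, 2), summed over sequences.

    A protein-coding barcode aligned in frame should show a frame with
    zero stops.  Uses the NCBI translation ``table`` (default 4, the
    mold/protozoan/coelenterate mitochondrial code used by sponges).
    """
    from Bio.Seq import Seq
    out = {}
    for frame in range(3):
        stops = 0
        for seq in aln.sequences:
            s = seq[frame:].replace("-", "")
            s = s[: len(s) - len(s) % 3]
            stops += str(Seq(s).translate(table=table)).count("*")
        out[frame] = stops
    return out
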