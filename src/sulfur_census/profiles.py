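"""Per-family profile models: construction, scoring, calibration and search.

A :class:`ProfileModel` is a profile hidden Markov model in the Plan7 mould:
one match state per well-occupied alignment column, with insert and delete
states between consecutive match positions. Scoring is best-path (Viterbi)
local alignment in log2-odds units ("bits") against a fixed background
distribution, with free entry into and exit from any match state — the
appropriate mode for partial metagenomic gene fragments.

Score cutoffs are derived per family from the training data
(leave-one-out positives vs different-function negatives), and bit scores
are converted to E-values through a Gumbel fit to background decoy scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from .alphabet import (
    AMBIG_INDEX,
    AMINO_ACIDS,
    BACKGROUND,
    GAP_CHARS,
    PAD_INDEX,
    degap,
    encode,
)
from .errors import (
    AlignmentShapeError,
    CalibrationMissingError,
    CalibrationUnderpoweredError,
    MissingTrainingError,
    NonSeparableTrainingWarning,
)

DEFAULT_SEED = 20200218

# Dirichlet prior counts for transition bundles; the strong M->M prior keeps
# per-position transition cost low for ungapped training alignments.
_PRIOR_MM, _PRIOR_MI, _PRIOR_MD = 2.0, 0.1, 0.1
_PRIOR_IM, _PRIOR_II = 1.0, 1.0
_PRIOR_DM, _PRIOR_DD = 1.0, 1.0

NEG_INF = float("-inf")


@dataclass
class TrainingSet:
    """Ratified positives (aligned) and different-function negatives for one family."""

    family_name: str
    positives: list[str]
    negatives: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.positives:
            raise MissingTrainingError(f"family {self.family_name}: no positive training sequences")
        lengths = {len(p) for p in self.positives}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"family {self.family_name}: aligned positives have ragged lengths {sorted(lengths)}"
            )

    @property
    def alignment_length(self) -> int:
        return len(self.positives[0])


@dataclass
class SearchHit:
    """One catalog gene scored above a family's cutoff."""

    gene_id: str
    family_name: str
    bit_score: float
    e_value: float
    verified: bool = False


@dataclass
class ProfileModel:
    """Profile HMM for one gene family (match emissions + transitions + calibration)."""

    family_name: str
    match_emissions: np.ndarray  # (L, 20), rows sum to 1
    transitions: np.ndarray  # (max(L-1, 0), 7): mm, mi, md, im, ii, dm, dd
    background: np.ndarray  # (20,)
    pseudocount_weight: float = 1.0
    score_cutoff: float | None = None
    evd_lambda: float | None = None
    evd_mu: float | None = None
    decoy_count: int = 0

    TRANSITION_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.score_cutoff is not None and self.evd_lambda is not None

    def validate(self) -> None:
        """Check all probability bundles normalize to 1 within 1e-9."""
        if self.length < 1:
            raise AlignmentShapeError("profile must have at least one match column")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise AlignmentShapeError("match emissions do not sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise AlignmentShapeError("background does not sum to 1")
        if self.transitions.size:
            t = self.transitions
            bundles = [t[:, 0] + t[:, 1] + t[:, 2], t[:, 3] + t[:, 4], t[:, 5] + t[:, 6]]
            for bundle in bundles:
                if not np.allclose(bundle, 1.0, atol=1e-9):
                    raise AlignmentShapeError("transition bundle does not sum to 1")
        if self.evd_lambda is not None and self.evd_lambda <= 0:
            raise AlignmentShapeError("evd_lambda must be positive")

    # --- score tables -----------------------------------------------------

    def emission_scores(self) -> np.ndarray:
        """Log2-odds emission table, (L, 22): 20 residues, ambiguity=0, pad=-inf."""
        esc = np.full((self.length, 22), NEG_INF)
        esc[:, :20] = np.log2(self.match_emissions / self.background[None, :])
        esc[:, AMBIG_INDEX] = 0.0
        return esc

    def log_transitions(self) -> np.ndarray:
        """Log2 transition table, same layout as ``transitions``."""
        with np.errstate(divide="ignore"):
            return np.log2(self.transitions)


def _column_gap_fraction(positives: list[str]) -> np.ndarray:
    length = len(positives[0])
    gaps = np.zeros(length)
    for seq in positives:
        for j, ch in enumerate(seq):
            if ch in GAP_CHARS:
                gaps[j] += 1
    return gaps / len(positives)


def build_profile(training: TrainingSet, pseudocount_weight: float = 1.0) -> ProfileModel:
    """Build a profile from an aligned positive training set.

    A column becomes a match state iff its gap fraction is below 0.5
    (majority occupancy). Emissions are observed residue frequencies blended
    with background-proportional pseudocounts of total mass
    ``pseudocount_weight``; transitions are estimated from the gap structure
    with Dirichlet priors.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    gap_fraction = _column_gap_fraction(training.positives)
    match_cols = np.where(gap_fraction < 0.5)[0]
    if match_cols.size == 0:
        raise AlignmentShapeError(
            f"family {training.family_name}: no column has majority occupancy"
        )
    L = match_cols.size
    col_to_match = {int(c): k for k, c in enumerate(match_cols)}
    match_set = set(col_to_match)

    counts = np.zeros((L, 20))
    # transition counts seeded with priors
    trans = np.tile(
        np.array([_PRIOR_MM, _PRIOR_MI, _PRIOR_MD, _PRIOR_IM, _PRIOR_II, _PRIOR_DM, _PRIOR_DD]),
        (max(L - 1, 1), 1),
    )
    if L == 1:
        trans = np.zeros((0, 7))

    tindex = {name: i for i, name in enumerate(ProfileModel.TRANSITION_NAMES)}

    for seq in training.positives:
        seq = seq.upper()
        # emission counts
        for j in match_set:
            ch = seq[j]
            if ch in GAP_CHARS:
                continue
            if ch == "X":
                counts[col_to_match[j]] += BACKGROUND
            else:
                idx = encode(ch)[0]
                counts[col_to_match[j], idx] += 1.0
        # state path: (kind, match position k)
        path: list[tuple[str, int]] = []
        last_match = -1
        for j, ch in enumerate(seq):
            if j in match_set:
                k = col_to_match[j]
                path.append(("M" if ch not in GAP_CHARS else "D", k))
                last_match = k
            elif ch not in GAP_CHARS:
                if 0 <= last_match:
                    path.append(("I", last_match))
        for (s0, k0), (s1, _k1) in zip(path, path[1:]):
            if k0 >= max(L - 1, 0) or trans.size == 0:
                continue
            name = (s0 + s1).lower()
            if name in tindex:
                trans[k0, tindex[name]] += 1.0

    emissions = counts + pseudocount_weight * BACKGROUND[None, :]
    emissions /= emissions.sum(axis=1, keepdims=True)

    if trans.size:
        trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
        trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
        trans[:, 5:7] /= trans[:, 5:7].sum(axis=1, keepdims=True)

    model = ProfileModel(
        family_name=training.family_name,
        match_emissions=emissions,
        transitions=trans,
        background=BACKGROUND.copy(),
        pseudocount_weight=pseudocount_weight,
    )
    model.validate()
    return model


# --- scoring ---------------------------------------------------------------


def _shift(arr: np.ndarray) -> np.ndarray:
    """Shift one consumed-residue index to the right, filling with -inf."""
    out = np.full_like(arr, NEG_INF)
    out[:, 1:] = arr[:, :-1]
    return out


def score_batch(profile: ProfileModel, sequences: list[str]) -> np.ndarray:
    """Best local log2-odds alignment score for each sequence, vectorized.

    Entry into any match state is free, as is exit after any match state;
    insert states emit at background (score 0 per inserted residue plus
    transition costs); delete states consume no residues.
    """
    if not sequences:
        return np.zeros(0)
    encoded = [encode(s) for s in sequences]
    n = len(encoded)
    N = max(len(e) for e in encoded)
    idx = np.full((n, N), PAD_INDEX, dtype=np.int64)
    for r, e in enumerate(encoded):
        idx[r, : len(e)] = e

    esc = profile.emission_scores()
    L = profile.length
    lt = profile.log_transitions() if L > 1 else np.zeros((0, 7))

    # DP arrays indexed by consumed residues i = 0..N
    def emit(k: int) -> np.ndarray:
        out = np.full((n, N + 1), NEG_INF)
        out[:, 1:] = esc[k][idx]
        return out

    M = emit(0)  # free entry: M_0(i) = e_0(x_i)
    D = np.full((n, N + 1), NEG_INF)
    I = None
    best = M.max(axis=1)

    for k in range(1, L):
        lmm, lmi, lmd, lim, lii, ldm, ldd = lt[k - 1]
        # insert state at k-1 (feeds M_k); affine running max over M_{k-1}
        i_idx = np.arange(N + 1)
        b = M + lmi - (i_idx + 1)[None, :] * lii
        with np.errstate(invalid="ignore"):
            c = np.maximum.accumulate(b, axis=1)
        I = np.full((n, N + 1), NEG_INF)
        I[:, 1:] = c[:, :-1] + (i_idx[1:])[None, :] * lii

        M_new = emit(k) + np.maximum.reduce(
            [np.zeros((n, N + 1)), _shift(M) + lmm, _shift(I) + lim, _shift(D) + ldm]
        )
        D_new = np.maximum(M + lmd, D + ldd)
        M, D = M_new, D_new
        best = np.maximum(best, M.max(axis=1))
    return best


def score_sequence(profile: ProfileModel, query: str) -> float:
    """Best local log2-odds alignment score of one query against the profile."""
    return float(score_batch(profile, [query])[0])


# --- calibration -----------------------------------------------------------


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Fit a Gumbel (extreme-value) distribution; returns (lambda, mu)."""
    mu, beta = gumbel_r.fit(scores)
    return 1.0 / beta, float(mu)


def calibrate_evalue(
    profile: ProfileModel,
    decoy_count: int = 1000,
    decoy_length: int | None = None,
    seed: int = DEFAULT_SEED,
) -> ProfileModel:
    """Fit the score-to-E-value map from background-sampled decoy sequences.

    Decoy maximal local scores follow an extreme-value (Gumbel) law; the
    fitted (lambda, mu) gives ``E(S) = database_size * exp(-lambda (S - mu))``
    at search time.
    """
    if decoy_count < 100:
        raise CalibrationUnderpoweredError(
            f"decoy_count={decoy_count} is below the minimum of 100"
        )
    if decoy_length is None:
        decoy_length = max(profile.length, 30)
    rng = np.random.default_rng(seed)
    decoys = [
        "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=decoy_length, p=profile.background))
        for _ in range(decoy_count)
    ]
    scores = score_batch(profile, decoys)
    lam, mu = fit_gumbel(scores)
    profile.evd_lambda = lam
    profile.evd_mu = mu
    profile.decoy_count = decoy_count
    profile.validate()
    return profile


def evalue(profile: ProfileModel, bit_score: float, database_size: int) -> float:
    """E-value of a bit score given the profile's Gumbel calibration."""
    if profile.evd_lambda is None or profile.evd_mu is None:
        raise CalibrationMissingError(f"profile {profile.family_name} has no EVD calibration")
    exponent = -profile.evd_lambda * (bit_score - profile.evd_mu)
    if exponent > 700.0:
        exponent = 700.0
    return database_size * math.exp(exponent)


def derive_family_cutoff(
    profile: ProfileModel,
    training: TrainingSet,
    margin: float = 10.0,
) -> float:
    """Derive the family bit-score cutoff from training-sequence cross-scores.

    The cutoff is the midpoint between the minimum leave-one-out positive
    score and the maximum negative score. Without negatives the cutoff is the
    minimum leave-one-out positive score minus ``margin``. If negatives
    overlap the positives the cutoff conservatively equals the minimum
    positive score and a warning is emitted.
    """
    positives = training.positives
    if len(positives) >= 2:
        loo_scores = []
        for i in range(len(positives)):
            rest = positives[:i] + positives[i + 1 :]
            loo_profile = build_profile(
                TrainingSet(training.family_name, rest), profile.pseudocount_weight
            )
            loo_scores.append(score_sequence(loo_profile, degap(positives[i])))
        min_pos = min(loo_scores)
    else:
        min_pos = score_sequence(profile, degap(positives[0]))

    if training.negatives:
        neg_scores = score_batch(profile, [degap(s) for s in training.negatives])
        max_neg = float(neg_scores.max())
        if max_neg >= min_pos:
            warnings.warn(
                f"family {training.family_name}: negatives overlap positives "
                f"(max negative {max_neg:.1f} >= min positive {min_pos:.1f}); "
                "cutoff set to min positive score",
                NonSeparableTrainingWarning,
            )
            cutoff = min_pos
        else:
            cutoff = 0.5 * (min_pos + max_neg)
    else:
        cutoff = min_pos - margin
    profile.score_cutoff = float(cutoff)
    return profile.score_cutoff


def search_catalog(
    profiles: list[ProfileModel],
    catalog: list,
    database_size: int | None = None,
) -> list[SearchHit]:
    """Score every catalog protein against every calibrated family profile.

    Returns hits at or above each family's score cutoff. A gene may hit
    several families at this stage; disambiguation happens during candidate
    verification. ``catalog`` entries need ``gene_id`` and ``protein``
    attributes.
    """
    for p in profiles:
        if not p.calibrated:
            raise CalibrationMissingError(
                f"profile {p.family_name} lacks cutoff or E-value calibration"
            )
    if not catalog:
        return []
    if database_size is None:
        database_size = len(catalog)
    sequences = [g.protein for g in catalog]
    hits: list[SearchHit] = []
    for p in profiles:
        scores = score_batch(p, sequences)
        for gene, s in zip(catalog, scores):
            if s >= p.score_cutoff:
                hits.append(
                    SearchHit(
                        gene_id=gene.gene_id,
                        family_name=p.family_name,
                        bit_score=float(s),
                        e_value=evalue(p, float(s), database_size),
                    )
                )
    return hits


# --- serialization ---------------------------------------------------------

_FORMAT_HEADER = "# sulfur-census profile v1"


def _fmt(x: float | None) -> str:
    return "NA" if x is None else format(x, ".12g")


def write_profile(profile: ProfileModel, path) -> None:
    """Write a profile to the versioned plain-text format (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write(_FORMAT_HEADER + "\n")
        fh.write(f"family\t{profile.family_name}\n")
        fh.write(f"length\t{profile.length}\n")
        fh.write(f"pseudocount_weight\t{_fmt(profile.pseudocount_weight)}\n")
        fh.write(f"score_cutoff\t{_fmt(profile.score_cutoff)}\n")
        fh.write(f"evd_lambda\t{_fmt(profile.evd_lambda)}\n")
        fh.write(f"evd_mu\t{_fmt(profile.evd_mu)}\n")
        fh.write(f"decoy_count\t{profile.decoy_count}\n")
        fh.write("background\t" + "\t".join(_fmt(v) for v in profile.background) + "\n")
        for k in range(profile.length):
            fh.write(
                f"match\t{k}\t" + "\t".join(_fmt(v) for v in profile.match_emissions[k]) + "\n"
            )
        for k in range(profile.transitions.shape[0]):
            fh.write(
                f"transition\t{k}\t" + "\t".join(_fmt(v) for v in profile.transitions[k]) + "\n"
            )


def read_profile(path) -> ProfileModel:
    """Read a profile written by :func:`write_profile`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _FORMAT_HEADER:
            raise ValueError(f"unrecognized profile format header: {header!r}")
        meta: dict[str, str] = {}
        match_rows: dict[int, list[float]] = {}
        trans_rows: dict[int, list[float]] = {}
        background = None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "match":
                match_rows[int(parts[1])] = [float(v) for v in parts[2:]]
            elif parts[0] == "transition":
                trans_rows[int(parts[1])] = [float(v) for v in parts[2:]]
            elif parts[0] == "background":
                background = np.array([float(v) for v in parts[1:]])
            else:
                meta[parts[0]] = parts[1]
    length = int(meta["length"])
    emissions = np.array([match_rows[k] for k in range(length)])
    transitions = (
        np.array([trans_rows[k] for k in range(length - 1)])
        if length > 1
        else np.zeros((0, 7))
    )

    def opt(key: str) -> float | None:
        return None if meta[key] == "NA" else float(meta[key])

    model = ProfileModel(
        family_name=meta["family"],
        match_emissions=emissions,
        transitions=transitions,
        background=background,
        pseudocount_weight=float(meta["pseudocount_weight"]),
        score_cutoff=opt("score_cutoff"),
        evd_lambda=opt("evd_lambda"),
        evd_mu=opt("evd_mu"),
        decoy_count=int(meta["decoy_count"]),
    )
    return model
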