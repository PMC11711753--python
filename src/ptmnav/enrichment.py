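"""Enrichment battery for PTM perturbation datasets.

Four complementary views of one regulated-peptide table:

* **Gene-centric / gene-centric-redundant set enrichment** — a single-sample
  rank statistic: items are sorted by value (descending), and the score is
  the integrated difference between the empirical cumulative distribution of
  signature-member ranks and that of the remaining ranks,

      score = sum_i [ECDF_sig(i) - ECDF_rest(i)] / N .

  Positive scores mean members concentrate at high ranks.  In the
  gene-centric variant duplicate keys collapse to the entry with maximum
  absolute value; the *redundant* variant keeps every occurrence, so a gene
  contributes once per regulated peptide it harbors.  p-values come from a
  member-set permutation null; both are FDR-controlled per experiment.

* **PTM-signature enrichment** — the same statistic over site-level keys,
  with signed membership: a signature member annotated with direction -1
  contributes with its value negated before ranking.

* **KSEA** — kinase activity as the standardized deviation of a kinase's
  substrate fold changes from the dataset background,
  z = (mean_substrates - mean_all) * sqrt(m) / sd_all, with a two-sided
  normal p-value.

* **Kinase motif enrichment** — peptides scored against per-kinase
  position-specific scoring matrices (sum of log2 weights over a -5..+4
  flanking window), converted to percentiles of a background distribution;
  each site keeps its top-k kinases, and per kinase and regulation direction
  a Fisher exact test asks whether regulated sites are overrepresented among
  the top-k hits.

All multiple-testing correction is Benjamini-Hochberg, applied per
experiment across signatures (set enrichment) or across kinases (KSEA,
motif).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .projection import KinaseSubstrateTable

# ---------------------------------------------------------------------------
# Profiles and signatures


@dataclass(frozen=True)
class Signature:
    """A named set of gene symbols or site keys, optionally signed.

    ``members`` maps key -> direction in {+1, -1}; unsigned signatures use
    +1 throughout.
    """

    signature_id: str
    members: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"signature {self.signature_id!r}: empty member set")
        object.__setattr__(self, "members", tuple(tuple(m) for m in self.members))

    @classmethod
    def from_keys(cls, signature_id: str, keys: Iterable[str]) -> "Signature":
        return cls(signature_id, tuple((k, 1) for k in keys))

    def sign_map(self) -> dict[str, int]:
        return dict(self.members)


@dataclass
class RankedProfile:
    """Ordered (key, value) list for one experiment.

    ``collapse_max_abs`` keeps, for each duplicated key, the entry with the
    maximum absolute value (first occurrence wins ties) — the gene-centric
    convention.  ``keep_all`` keeps every occurrence — the gene-centric
    *redundant* convention, in which a key is counted once per peptide.
    """

    items: list[tuple[str, float]]
    duplicate_policy: str = "collapse_max_abs"

    def __post_init__(self):
        if self.duplicate_policy not in ("collapse_max_abs", "keep_all"):
            raise ValueError(f"unknown duplicate_policy {self.duplicate_policy!r}")
        if self.duplicate_policy == "collapse_max_abs":
            best: dict[str, tuple[str, float]] = {}
            for key, value in self.items:
                if key not in best or abs(value) > abs(best[key][1]):
                    best[key] = (key, value)
            self.items = list(best.values())

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class EnrichmentResult:
    signature_id: str
    overlap: int
    score: float  # NaN when undefined
    p: float = math.nan
    p_adj: float = math.nan


def _ranked_arrays(profile: RankedProfile, signature: Signature):
    """Sort (stable, descending by value after sign adjustment) and return
    the membership indicator plus distinct-key overlap."""
    signs = signature.sign_map()
    adjusted = [
        (key, signs[key] * value if key in signs else value) for key, value in profile.items
    ]
    # stable descending sort: ties keep input order
    order = sorted(range(len(adjusted)), key=lambda i: -adjusted[i][1])
    member = np.array([adjusted[i][0] in signs for i in order], dtype=bool)
    overlap = len({key for key, _ in adjusted if key in signs})
    return member, overlap


def enrichment_score(profile: RankedProfile, signature: Signature) -> tuple[float, int]:
    """Integrated ECDF-difference enrichment score and distinct-key overlap.

    With ``keep_all`` profiles every occurrence of a member key contributes
    (redundant counting).  Zero overlap, or a signature swallowing the whole
    profile, yields a NaN score (reported, not raised).
    """
    member, overlap = _ranked_arrays(profile, signature)
    n = len(member)
    m = int(member.sum())
    if m == 0:
        return math.nan, 0
    if m == n:
        return math.nan, overlap
    cum_sig = np.cumsum(member) / m
    cum_rest = np.cumsum(~member) / (n - m)
    score = float(np.sum(cum_sig - cum_rest) / n)
    return score, overlap


def _perm_scores(member_count: int, n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Scores of random equal-size member sets, via the closed form
    score = [sum_j (n - pos_j)/m - (T - sum_j (n - pos_j))/(n - m)] / n
    with T = n(n+1)/2 over 0-based member positions pos_j."""
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, member_count - 1, axis=1)[:, :member_count]
    weight = (n - pos).sum(axis=1).astype(float)
    total = n * (n + 1) / 2.0
    m = member_count
    return (weight / m - (total - weight) / (n - m)) / n


def permutation_pvalues(
    profile: RankedProfile,
    signatures: Sequence[Signature],
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Permutation p-values for a battery of signatures on one profile.

    Per signature: p = (1 + #{permuted |score| >= observed |score|}) /
    (1 + n_perm), permuting the member *set* (random equal-size sets of
    profile positions).  BH adjustment runs across the signatures of this
    profile; NaN-scored signatures are excluded from the BH family.
    Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(profile)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    testable: list[int] = []
    for idx, signature in enumerate(signatures):
        score, overlap = enrichment_score(profile, signature)
        if math.isnan(score):
            results.append(EnrichmentResult(signature.signature_id, overlap, math.nan))
            continue
        member, _ = _ranked_arrays(profile, signature)
        m = int(member.sum())
        perm = _perm_scores(m, n, n_perm, rng)
        p = (1.0 + float(np.sum(np.abs(perm) >= abs(score)))) / (1.0 + n_perm)
        results.append(EnrichmentResult(signature.signature_id, overlap, score, p))
        pvals.append(p)
        testable.append(len(results) - 1)
    if pvals:
        adjusted = bh_adjust(pvals)
        for i, p_adj in zip(testable, adjusted):
            r = results[i]
            results[i] = EnrichmentResult(r.signature_id, r.overlap, r.score, r.p, p_adj)
    return results


def rank_pathways(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Pathway ordering for display: descending |score|, NaN-scored last,
    stable among ties."""
    indexed = list(enumerate(results))
    indexed.sort(key=lambda t: (math.isnan(t[1].score), -abs(t[1].score) if not math.isnan(t[1].score) else 0.0, t[0]))
    return [r for _, r in indexed]


# ---------------------------------------------------------------------------
# KSEA


@dataclass(frozen=True)
class KinaseActivity:
    kinase: str
    z_score: float
    p: float
    p_adj: float
    n_substrates: int


def site_key(substrate: str, residue: str, position: int) -> str:
    """Canonical site key, e.g. ("SOS1", "S", 1134) -> "SOS1_S1134"."""
    return f"{substrate.upper()}_{residue.upper()}{position}"


def ksea(
    fold_changes: RankedProfile | Sequence[tuple[str, float]],
    table: KinaseSubstrateTable,
    min_substrates: int = 3,
) -> list[KinaseActivity]:
    """Kinase-substrate enrichment: mean substrate fold change vs background.

    ``fold_changes`` maps site keys (see :func:`site_key`) to log2 fold
    changes; duplicates collapse by maximum absolute value.  For each kinase
    with m >= min_substrates matched substrate sites,
    z = (mean_s - mean_all) * sqrt(m) / sd_all (sd with ddof=1), two-sided
    normal p, BH across reported kinases.  A zero background sd makes every
    z undefined and raises.
    """
    if not isinstance(fold_changes, RankedProfile):
        fold_changes = RankedProfile(list(fold_changes), "collapse_max_abs")
    else:
        fold_changes = RankedProfile(list(fold_changes.items), "collapse_max_abs")
    values = {key.upper(): value for key, value in fold_changes.items}
    all_values = np.array(list(values.values()), dtype=float)
    if len(all_values) < 2:
        raise ValueError("KSEA needs at least 2 sites")
    mean_all = float(all_values.mean())
    sd_all = float(all_values.std(ddof=1))
    if sd_all == 0.0:
        raise ValueError("background fold changes have zero standard deviation; z undefined")

    activities = []
    pvals = []
    for kinase in table.kinases():
        matched = []
        seen: set[str] = set()
        for row in table.substrates_of(kinase):
            key = site_key(row.substrate, row.residue, row.position)
            if key in values and key not in seen:
                matched.append(values[key])
                seen.add(key)
        m = len(matched)
        if m < min_substrates:
            continue
        z = (float(np.mean(matched)) - mean_all) * math.sqrt(m) / sd_all
        p = 2.0 * float(stats.norm.sf(abs(z)))
        activities.append((kinase, z, p, m))
        pvals.append(p)
    adjusted = bh_adjust(pvals) if pvals else []
    return [
        KinaseActivity(kinase, z, p, p_adj, m)
        for (kinase, z, p, m), p_adj in zip(activities, adjusted)
    ]


# ---------------------------------------------------------------------------
# Motif enrichment


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


@dataclass
class PSSM:
    """Positional residue preferences of one kinase around the
    phospho-acceptor (positions -5..+4 by default); weights are positive and
    scored as sums of log2 weights."""

    kinase: str
    weights: dict[int, dict[str, float]]  # position -> residue -> weight

    def __post_init__(self):
        positions = sorted(self.weights)
        if positions != list(range(positions[0], positions[0] + len(positions))):
            raise ValueError(f"PSSM {self.kinase}: positions must be contiguous")
        for pos, row in self.weights.items():
            for aa, w in row.items():
                if w <= 0:
                    raise ValueError(f"PSSM {self.kinase}: non-positive weight at {pos}/{aa}")

    @property
    def positions(self) -> list[int]:
        return sorted(self.weights)

    @property
    def window(self) -> int:
        return len(self.weights)

    def score(self, sequence: str) -> float:
        """Sum of log2 weights for the residues of a centered flanking
        sequence; padding (and residues absent from the matrix) is skipped."""
        if len(sequence) != self.window:
            raise ValueError(
                f"sequence length {len(sequence)} != PSSM window {self.window}"
            )
        total = 0.0
        for pos, residue in zip(self.positions, sequence.upper()):
            row = self.weights[pos]
            if residue in row:
                total += math.log2(row[residue])
        return total

    def argmax_sequence(self) -> str:
        return "".join(
            max(self.weights[pos], key=lambda aa: (self.weights[pos][aa], aa))
            for pos in self.positions
        )


@dataclass(frozen=True)
class MotifEnrichmentResult:
    kinase: str
    direction: str
    overlap: int  # regulated sites with this kinase in their top-k
    odds_ratio: float
    p: float
    p_adj: float


def score_percentile(score: float, background: np.ndarray) -> float:
    """Fraction of the background distribution <= score."""
    background = np.sort(np.asarray(background, dtype=float))
    return float(np.searchsorted(background, score, side="right")) / len(background)


def motif_enrichment(
    peptides: Sequence[tuple[str, str]],
    pssms: Sequence[PSSM],
    background_scores: dict[str, np.ndarray],
    top_k: int = 15,
) -> list[MotifEnrichmentResult]:
    """Kinase motif over-representation among regulated peptides.

    Each (flanking sequence, regulation) pair is scored against every PSSM,
    scores become background percentiles, and the ``top_k`` kinases per site
    are kept (ties broken by kinase name for determinism).  Per direction in
    {up, down} and per kinase appearing in any top-k list, a 2x2 Fisher
    exact test (two-sided) contrasts regulated vs other sites against
    top-k membership, BH-corrected across kinases within the direction.
    """
    for pssm in pssms:
        if pssm.kinase not in background_scores or len(background_scores[pssm.kinase]) == 0:
            raise ValueError(f"missing background score distribution for {pssm.kinase}")

    top_hits: list[set[str]] = []
    regulations: list[str] = []
    for idx, (sequence, regulation) in enumerate(peptides):
        percentiles = []
        for pssm in pssms:
            try:
                s = pssm.score(sequence)
            except ValueError as exc:
                raise ValueError(f"peptide #{idx}: {exc}") from exc
            percentiles.append((pssm.kinase, score_percentile(s, background_scores[pssm.kinase])))
        percentiles.sort(key=lambda t: (-t[1], t[0]))
        top_hits.append({k for k, _ in percentiles[:top_k]})
        regulations.append(regulation)

    kinases = sorted({k for hits in top_hits for k in hits})
    results: list[MotifEnrichmentResult] = []
    for direction in ("up", "down"):
        reg = np.array([r == direction for r in regulations], dtype=bool)
        if not reg.any():
            continue
        rows = []
        for kinase in kinases:
            in_top = np.array([kinase in hits for hits in top_hits], dtype=bool)
            a = int(np.sum(reg & in_top))
            b = int(np.sum(reg & ~in_top))
            c = int(np.sum(~reg & in_top))
            d = int(np.sum(~reg & ~in_top))
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((kinase, a, float(odds), float(p)))
        adjusted = bh_adjust([p for *_, p in rows])
        for (kinase, a, odds, p), p_adj in zip(rows, adjusted):
            results.append(MotifEnrichmentResult(kinase, direction, a, odds, p, p_adj))
    return results


# ---------------------------------------------------------------------------
# Signature / PSSM text formats


def load_signatures(source) -> list[Signature]:
    """Read a GMT-like signature database.

    One signature per line: id, description, then tab-separated member keys;
    a member may carry a ``;+1`` or ``;-1`` suffix giving its direction sign
    (PTM-centric signatures).
    """
    from pathlib import Path

    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else (
        source if isinstance(source, str) else source.read()
    )
    signatures = []
    for line_no, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {line_no}: expected id, description and >=1 member")
        members = []
        for token in parts[2:]:
            if not token:
                continue
            if ";" in token:
                key, sign_s = token.rsplit(";", 1)
                sign = int(sign_s)
                if sign not in (1, -1):
                    raise ValueError(f"GMT line {line_no}: sign must be +1/-1, got {sign_s!r}")
            else:
                key, sign = token, 1
            members.append((key, sign))
        signatures.append(Signature(parts[0], tuple(members)))
    return signatures


def load_pssm_tsv(source, kinase: str) -> PSSM:
    """Read one PSSM from TSV: header row of positions, then one row per
    amino acid (residue letter first)."""
    from pathlib import Path

    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else (
        source if isinstance(source, str) else source.read()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    positions = [int(tok) for tok in lines[0].split("\t")[1:]]
    weights: dict[int, dict[str, float]] = {pos: {} for pos in positions}
    for line in lines[1:]:
        parts = line.split("\t")
        aa = parts[0]
        for pos, value in zip(positions, parts[1:]):
            weights[pos][aa] = float(value)
    return PSSM(kinase, weights)


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up with monotonicity enforcement; output >= input
    elementwise and equivariant under permutation of the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adjusted]
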