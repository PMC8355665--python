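"""Per-α-chain substitution rates.

Two routes to the same quantity — the rate of collagen (I) sequence
evolution per chain, in substitutions per site per million years (Ma):

1. **Clock-summary arithmetic** (:func:`per_chain_rate`): given the mean
   clock rate ``m`` and the relative partition-rate multipliers ``r_p`` from
   a Bayesian relaxed-clock run's parameter-summary (``.pstat``) table, the
   per-site rate of chain ``p`` is ``m·r_p`` and the whole-chain rate is
   ``R_p = m·r_p·L_p`` substitutions per Ma for a chain of ``L_p`` sites.
2. **Fixed-chronogram maximum likelihood** (:class:`PartitionRateModel`):
   with a time-calibrated tree held fixed, the three per-site rates are the
   only free parameters of a partitioned likelihood under an empirical
   amino-acid model (Dayhoff by default), computed by the pruning
   recursion with branch lengths ``site_rate × branch duration``.

Gaps and ``X`` are treated as missing data, so a taxon whose α3 partition
is dash-filled contributes nothing to the α3 likelihood.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .dayhoff import MODEL_ORDER, SubstitutionModel, dayhoff_model
from .records import CHAIN_ORDER, ConcatenatedAlignment

logger = logging.getLogger(__name__)

#: Missing-data code used in encoded alignments.
MISSING = 20


class ClockSummaryError(ValueError):
    """Required clock parameters absent from a summary table."""


class DegenerateInputError(ValueError):
    """Input admits no meaningful rate estimate (e.g. zero-duration tree)."""


# ---------------------------------------------------------------------------
# clock-summary arithmetic

@dataclass
class ClockSummary:
    """Mean clock rate and relative partition-rate multipliers.

    ``mean_clockrate`` is in substitutions per site per Ma; multipliers are
    dimensionless with mean 1 across partitions by the usual convention.
    """

    mean_clockrate: float
    relative_partition_rates: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.mean_clockrate > 0:
            raise ClockSummaryError("mean clock rate must be positive")
        for chain, r in self.relative_partition_rates.items():
            if not r > 0:
                raise ClockSummaryError(f"relative rate for {chain} must be positive")

    def site_rate(self, chain: str) -> float:
        return self.mean_clockrate * self.relative_partition_rates[chain]


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ChainRateTable:
    """Per-chain site and whole-chain substitution rates, plus a mean row.

    ``chain_rate = site_rate × length`` exactly; rounding happens only in
    :meth:`display` (half-up, 1 decimal for chain rates).
    """

    table: pd.DataFrame  # index: chains + 'mean'; columns: site_rate, length, chain_rate

    @property
    def mean_chain_rate(self) -> float:
        return float(self.table.loc["mean", "chain_rate"])

    def display(self) -> pd.DataFrame:
        """Presentation rounding: site rates to 5 dp, lengths to integers,
        chain rates half-up to 1 dp."""
        disp = pd.DataFrame(index=self.table.index)
        disp["site_rate"] = [
            _round_half_up(v, 5) for v in self.table["site_rate"]
        ]
        disp["length"] = [
            int(_round_half_up(v, 0)) for v in self.table["length"]
        ]
        disp["chain_rate"] = [
            _round_half_up(v, 1) for v in self.table["chain_rate"]
        ]
        return disp

    def to_tsv(self, path) -> None:
        self.display().to_csv(path, sep="\t", index_label="partition")


def per_chain_rate(
    summary: ClockSummary, lengths: dict[str, int]
) -> ChainRateTable:
    """Whole-chain substitution rates from clock-summary parameters.

    For each chain, multiplies the mean clock rate by the chain's relative
    partition rate (giving substitutions/site/Ma) and then by the number of
    sites in the chain (giving substitutions/Ma).  The mean row is the
    arithmetic mean of the three chains.
    """
    rows = {}
    for chain in CHAIN_ORDER:
        if chain not in lengths:
            raise KeyError(f"no length given for chain {chain}")
        if chain not in summary.relative_partition_rates:
            raise KeyError(f"no relative rate for chain {chain}")
        site_rate = summary.site_rate(chain)
        L = lengths[chain]
        if not L > 0:
            raise ValueError(f"length for {chain} must be positive")
        rows[chain] = (site_rate, float(L), site_rate * L)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["site_rate", "length", "chain_rate"]
    )
    df.loc["mean"] = df.mean(axis=0)
    return ChainRateTable(table=df)


_CLOCKRATE_RE = re.compile(r"clockrate", re.IGNORECASE)
# partition-rate multipliers in the common Bayesian summary dialect:
# m{1}, m{2}... or ratemultiplier{N}; partition index N maps to chain order
_MULTIPLIER_RE = re.compile(r"^(?:m|ratemultiplier)\{(\d+)\}$", re.IGNORECASE)


def read_clock_summary(path) -> ClockSummary:
    """Parse a ``.pstat``-style whitespace-delimited parameter summary.

    Expects a header row containing ``Mean``; parameter rows follow.  The
    clock rate is the row whose name contains ``clockrate``; relative
    partition rates are rows named ``m{N}`` (or ``ratemultiplier{N}``) with
    partition index N assigned to chains in α1, α2, α3 order.  Unmatched
    parameters are ignored with a log message.
    """
    clockrate: float | None = None
    multipliers: dict[int, float] = {}
    mean_col: int | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("[", "#")):
                continue
            fields = line.split()
            if mean_col is None:
                lowered = [f.lower().strip(".") for f in fields]
                if "mean" in lowered:
                    mean_col = lowered.index("mean")
                    continue
                raise ClockSummaryError(f"{path}: no header row with a Mean column")
            name = fields[0]
            try:
                value = float(fields[mean_col])
            except (IndexError, ValueError):
                logger.info("skipping unparseable summary row %r", name)
                continue
            if _CLOCKRATE_RE.search(name):
                clockrate = value
            else:
                m = _MULTIPLIER_RE.match(name)
                if m:
                    multipliers[int(m.group(1))] = value
                else:
                    logger.info("ignoring parameter %r", name)
    if mean_col is None:
        raise ClockSummaryError(f"{path}: empty summary file")
    if clockrate is None:
        raise ClockSummaryError(f"{path}: no clockrate row found")
    rel = {
        chain: multipliers.get(i + 1, 1.0) for i, chain in enumerate(CHAIN_ORDER)
    }
    if not multipliers:
        logger.warning("%s: no partition-rate multipliers found; assuming 1.0", path)
    return ClockSummary(
        mean_clockrate=clockrate, relative_partition_rates=rel, source=str(path)
    )


# ---------------------------------------------------------------------------
# likelihood on a fixed chronogram

def encode_alignment_block(rows: list[str]) -> np.ndarray:
    """Encode sequence rows as integer codes; gap/X become the missing code."""
    lookup = np.full(128, -1, dtype=np.int8)
    for i, aa in enumerate(MODEL_ORDER):
        lookup[ord(aa)] = i
    lookup[ord("-")] = MISSING
    lookup[ord("X")] = MISSING
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    codes = lookup[arr]
    if (codes < 0).any():
        raise ValueError("unencodable character in alignment block")
    return codes


def _site_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    return patterns.T, counts  # (ntaxa × npatterns), counts


def _pruning_partition_loglik(
    tree: dendropy.Tree,
    taxon_row: dict[str, int],
    patterns: np.ndarray,
    counts: np.ndarray,
    site_rate: float,
    model: SubstitutionModel,
) -> float:
    """Felsenstein pruning over compressed site patterns for one partition."""
    npat = patterns.shape[1]
    tip_partials = np.vstack([np.eye(20), np.ones(20)])  # code -> conditional vector
    partials: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = taxon_row[node.taxon.label]
            partials[id(node)] = tip_partials[patterns[row]]
            logscale[id(node)] = np.zeros(npat)
        else:
            part = np.ones((npat, 20))
            scale = np.zeros(npat)
            for child in node.child_nodes():
                duration = child.edge.length or 0.0
                P = model.transition_probabilities(site_rate * duration)
                part = part * (partials[id(child)] @ P.T)
                scale = scale + logscale[id(child)]
            mx = part.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            partials[id(node)] = part / mx[:, None]
            logscale[id(node)] = scale + np.log(mx)
    root = tree.seed_node
    site_lik = partials[id(root)] @ model.frequencies
    return float(((np.log(site_lik) + logscale[id(root)]) * counts).sum())


class PartitionRateModel:
    """Partitioned ML rate model on a fixed time-calibrated tree.

    Given a concatenated alignment, a chronogram with branch durations in
    Ma and a substitution model, the only free parameters are the three
    per-chain site rates.  ``fit`` maximises the pruning likelihood for
    each partition independently (partitions share the chronogram but
    nothing else) and returns a :class:`PartitionRateResults`.
    """

    def __init__(
        self,
        alignment: ConcatenatedAlignment,
        chronogram: dendropy.Tree,
        model: SubstitutionModel | None = None,
    ):
        self.alignment = alignment
        self.chronogram = chronogram
        self.model = model or dayhoff_model()
        tree_labels = {lf.taxon.label for lf in chronogram.leaf_node_iter()}
        if tree_labels != set(alignment.taxa):
            raise ValueError(
                "chronogram leaf set does not match alignment taxa: "
                f"only-in-tree={sorted(tree_labels - set(alignment.taxa))[:3]} "
                f"only-in-alignment={sorted(set(alignment.taxa) - tree_labels)[:3]}"
            )
        self._taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
        self._patterns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chain in CHAIN_ORDER:
            block = alignment.chain_block(chain)
            codes = encode_alignment_block(block)
            if (codes == MISSING).all():
                raise DegenerateInputError(
                    f"partition {chain} is entirely missing data"
                )
            self._patterns[chain] = _site_patterns(codes)

    def loglik_partition(self, chain: str, site_rate: float) -> float:
        """Log-likelihood of one chain partition at the given site rate."""
        if site_rate < 0:
            raise ValueError("site rate must be non-negative")
        patterns, counts = self._patterns[chain]
        return _pruning_partition_loglik(
            self.chronogram, self._taxon_row, patterns, counts, site_rate, self.model
        )

    def loglik(self, site_rates: dict[str, float]) -> float:
        """Joint log-likelihood across the three partitions."""
        return sum(self.loglik_partition(c, site_rates[c]) for c in CHAIN_ORDER)

    def fit(
        self,
        rate_bounds: tuple[float, float] = (1e-7, 0.5),
        xatol: float = 1e-10,
        ci_level_drop: float = 1.92,
    ) -> "PartitionRateResults":
        """Maximise the likelihood over the three per-chain site rates.

        Uses bounded scalar optimisation per partition; confidence
        intervals are profile-likelihood bounds at a log-likelihood drop of
        ``ci_level_drop`` (1.92 ≈ 95% for one parameter).
        """
        total = sum(e.length or 0.0 for e in self.chronogram.edges())
        if total <= 0:
            raise DegenerateInputError(
                "chronogram has zero total duration; rates are unidentifiable"
            )
        estimates: dict[str, float] = {}
        intervals: dict[str, tuple[float, float]] = {}
        logliks: dict[str, float] = {}
        for chain in CHAIN_ORDER:
            res = minimize_scalar(
                lambda r, c=chain: -self.loglik_partition(c, r),
                bounds=rate_bounds,
                method="bounded",
                options={"xatol": xatol},
            )
            if not res.success:
                raise RuntimeError(
                    f"rate optimisation failed for {chain}: {res.message}"
                )
            mle = float(res.x)
            lmax = -float(res.fun)
            estimates[chain] = mle
            logliks[chain] = lmax

            def drop(r, c=chain):
                return self.loglik_partition(c, r) - (lmax - ci_level_drop)

            lo_bound, hi_bound = rate_bounds
            lo = lo_bound if drop(lo_bound) > 0 else brentq(drop, lo_bound, mle)
            hi = hi_bound if drop(hi_bound) > 0 else brentq(drop, mle, hi_bound)
            intervals[chain] = (float(lo), float(hi))
        return PartitionRateResults(
            model=self,
            site_rates=estimates,
            conf_ints=intervals,
            partition_logliks=logliks,
        )


@dataclass
class PartitionRateResults:
    """ML estimates of per-chain site rates with profile-likelihood CIs."""

    model: PartitionRateModel
    site_rates: dict[str, float]
    conf_ints: dict[str, tuple[float, float]]
    partition_logliks: dict[str, float]

    @property
    def loglik(self) -> float:
        return sum(self.partition_logliks.values())

    def chain_lengths(self) -> dict[str, int]:
        parts = self.model.alignment.partitions
        return {c: parts[c][1] - parts[c][0] + 1 for c in CHAIN_ORDER}

    def rate_table(self) -> ChainRateTable:
        """Whole-chain rates ``site_rate × length`` with a mean row."""
        lengths = self.chain_lengths()
        rows = {
            c: (self.site_rates[c], float(lengths[c]), self.site_rates[c] * lengths[c])
            for c in CHAIN_ORDER
        }
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["site_rate", "length", "chain_rate"]
        )
        df.loc["mean"] = df.mean(axis=0)
        return ChainRateTable(table=df)

    def summary(self) -> str:
        lengths = self.chain_lengths()
        lines = [
            "Partitioned ML substitution rates (fixed chronogram, "
            f"{self.model.model.name} model)",
            f"taxa: {self.model.alignment.n_taxa}   "
            f"log-likelihood: {self.loglik:.2f}",
            "",
            f"{'partition':<10}{'sites':>7}{'rate/site/Ma':>15}"
            f"{'95% CI':>24}{'rate/chain/Ma':>15}",
        ]
        for c in CHAIN_ORDER:
            lo, hi = self.conf_ints[c]
            lines.append(
                f"{c:<10}{lengths[c]:>7}{self.site_rates[c]:>15.6f}"
                f"{f'[{lo:.6f}, {hi:.6f}]':>24}"
                f"{self.site_rates[c] * lengths[c]:>15.2f}"
            )
        mean_site = np.mean([self.site_rates[c] for c in CHAIN_ORDER])
        mean_chain = np.mean(
            [self.site_rates[c] * lengths[c] for c in CHAIN_ORDER]
        )
        lines.append(
            f"{'mean':<10}{round(np.mean(list(lengths.values()))):>7}"
            f"{mean_site:>15.6f}{'':>24}{mean_chain:>15.2f}"
        )
        return "\n".join(lines)


def pruning_loglik(
    alignment: ConcatenatedAlignment,
    chronogram: dendropy.Tree,
    site_rates: dict[str, float],
    model: SubstitutionModel | None = None,
) -> float:
    """Partitioned pruning log-likelihood at fixed per-chain site rates.

    Convenience wrapper over :class:`PartitionRateModel`.  On a tree of
    total duration zero this reduces to the closed form
    ``sum(log pi[residue])`` over observed residues (identical sequences).
    """
    return PartitionRateModel(alignment, chronogram, model).loglik(site_rates)


def estimate_partition_rates(
    alignment: ConcatenatedAlignment,
    chronogram: dendropy.Tree,
    model: SubstitutionModel | None = None,
    **fit_kwargs,
) -> PartitionRateResults:
    """ML per-chain site rates on a fixed chronogram (see
    :class:`PartitionRateModel`)."""
    return PartitionRateModel(alignment, chronogram, model).fit(**fit_kwargs)
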