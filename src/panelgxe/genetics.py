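"""Genotype quality control and linkage-disequilibrium structure.

Operations on a subjects x SNPs table of minor-allele counts (0/1/2):
minor-allele frequency, the 1-df Hardy-Weinberg chi-square test with an
exclusion rule, two-locus haplotype frequency estimation from unphased
genotypes by EM, the normalized LD coefficient |D'|, within-gene LD
block formation, and one-SNP-per-block pruning.

The EM treats each subject's two-locus genotype as an unordered pair of
haplotypes drawn from a four-category haplotype distribution (AB, Ab,
aB, ab); only double heterozygotes have ambiguous phase and they are
split fractionally between AB/ab and Ab/aB in the E-step in proportion
to the current haplotype-frequency products (the classic two-locus EM
behind Haploview-style |D'| estimates).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError

logger = logging.getLogger(__name__)

#: Haplotype order used everywhere: alleles of (snp_a, snp_b), 1 = minor.
HAPLOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))  # ab, aB, Ab, AB by minor allele


@dataclass
class GenotypeTable:
    """Subjects x SNPs additive-coded genotype matrix plus SNP metadata.

    ``genotypes``: DataFrame indexed by subject_id, one 0/1/2 (or NaN)
    column per SNP.  ``snp_info``: DataFrame indexed by snp_id with at
    least a ``gene`` column; QC adds ``maf``, ``maf_flipped``,
    ``hwe_chi2``, ``hwe_p`` and ``monomorphic``.
    """

    genotypes: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self):
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("genotype values must be 0, 1, 2 or missing")
        if not self.snp_info.index.equals(pd.Index(self.genotypes.columns)):
            self.snp_info = self.snp_info.reindex(self.genotypes.columns)

    @property
    def snp_ids(self):
        return list(self.genotypes.columns)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeTable":
        return GenotypeTable(self.genotypes[list(snp_ids)].copy(),
                             self.snp_info.loc[list(snp_ids)].copy())

    def with_qc(self) -> "GenotypeTable":
        """Return a copy whose snp_info carries observed MAF and HWE stats."""
        info = self.snp_info.copy()
        rows = []
        for snp in self.snp_ids:
            col = self.genotypes[snp]
            maf, flipped = minor_allele_frequency(col)
            counts = genotype_counts(col)
            hwe = hwe_test(*counts)
            rows.append((maf, flipped, hwe.chi2, hwe.p, hwe.monomorphic))
        info[["maf", "maf_flipped", "hwe_chi2", "hwe_p", "monomorphic"]] = rows
        return GenotypeTable(self.genotypes.copy(), info)

    def to_csv(self, genotype_path, snp_path):
        self.genotypes.to_csv(genotype_path, index_label="subject_id")
        self.snp_info.to_csv(snp_path, index_label="snp_id")

    @classmethod
    def from_csv(cls, genotype_path, snp_path) -> "GenotypeTable":
        geno = pd.read_csv(genotype_path, index_col="subject_id")
        info = pd.read_csv(snp_path, index_col="snp_id")
        return cls(geno, info)


def genotype_counts(column) -> tuple[int, int, int]:
    """Counts (n0, n1, n2) of coded-allele copies, ignoring missing."""
    v = pd.Series(column).dropna().to_numpy(dtype=float)
    return tuple(int(np.sum(v == k)) for k in (0, 1, 2))


def minor_allele_frequency(column) -> tuple[float, bool]:
    """Frequency of the coded allele, re-oriented to the minor allele.

    Returns ``(maf, flipped)`` where ``flipped`` is True when the coded
    allele was actually the major one (frequency > 0.5).
    """
    v = pd.Series(column).dropna().to_numpy(dtype=float)
    if len(v) == 0:
        raise DataError("all genotypes missing")
    freq = v.sum() / (2 * len(v))
    if freq > 0.5:
        return 1.0 - freq, True
    return float(freq), False


class HweResult(NamedTuple):
    chi2: float
    p: float
    monomorphic: bool


def hwe_test(n0: int, n1: int, n2: int) -> HweResult:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    Observed genotype counts (n0, n1, n2) are compared with
    n*(p^2, 2pq, q^2) at the sample allele frequency.  A monomorphic
    SNP admits no test and returns p = 1 with a flag.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise DataError("hwe_test needs at least one genotype")
    q = (n1 + 2 * n2) / (2 * n)  # coded-allele frequency
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1.0, True)
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)), False)


def apply_hwe_exclusion(table: GenotypeTable, alpha: float = 1e-3
                        ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop SNPs whose HWE p-value is below ``alpha``.

    Returns the filtered table and an exclusion log (snp_id, gene,
    hwe_p).  ``alpha=0`` excludes nothing.
    """
    qc = table.with_qc()
    info = qc.snp_info
    excluded = info.index[info["hwe_p"] < alpha]
    log = info.loc[excluded, ["gene", "hwe_p"]].reset_index()
    for _, row in log.iterrows():
        logger.info("HWE exclusion: %s (p=%.3g)", row["snp_id"], row["hwe_p"])
    keep = [s for s in qc.snp_ids if s not in set(excluded)]
    if not keep:
        logger.warning("all SNPs excluded by the HWE filter")
    return qc.subset(keep), log


# ---------------------------------------------------------------------------
# Two-locus haplotype EM and |D'|


@dataclass
class EmResult:
    freqs: np.ndarray          # (f_ab, f_aB, f_Ab, f_AB) per HAPLOTYPES order
    loglik: float
    n_iter: int
    loglik_trace: list = field(default_factory=list, repr=False)

    @property
    def f_AB(self) -> float:
        return float(self.freqs[3])


def _pair_counts(geno_a, geno_b) -> np.ndarray:
    """3x3 table of joint genotype counts over pairwise-complete subjects."""
    a = pd.Series(geno_a).to_numpy(dtype=float)
    b = pd.Series(geno_b).to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok].astype(int), b[ok].astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1.0)
    return counts


def two_locus_loglik(counts: np.ndarray, freqs) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table.

    Genotype-pair probabilities assume random union of haplotypes:
    P(g_a, g_b) = sum over ordered haplotype pairs consistent with the
    diplotype of the product of haplotype frequencies.
    """
    f = {h: freqs[i] for i, h in enumerate(HAPLOTYPES)}
    ll = 0.0
    for ga in range(3):
        for gb in range(3):
            if counts[ga, gb] == 0:
                continue
            prob = 0.0
            for h1, h2 in itertools.product(HAPLOTYPES, repeat=2):
                if h1[0] + h2[0] == ga and h1[1] + h2[1] == gb:
                    prob += f[h1] * f[h2]
            ll += counts[ga, gb] * np.log(max(prob, 1e-300))
    return float(ll)


def em_haplotype_freqs(geno_a, geno_b, tol: float = 1e-8,
                       max_iter: int = 1000) -> EmResult:
    """EM estimate of two-locus haplotype frequencies from unphased data.

    Initialized at linkage-equilibrium products of the sample allele
    frequencies; iterates until the largest absolute frequency change is
    below ``tol``.  The log-likelihood is non-decreasing by the usual EM
    argument; the trace is retained so callers can assert it.
    """
    counts = _pair_counts(geno_a, geno_b)
    n = counts.sum()
    if n < 2:
        raise DataError("need at least 2 pairwise-complete subjects")
    pa = (counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n)
    pb = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    # order: ab, aB, Ab, AB
    freqs = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()

    # Haplotype counts fixed by unambiguous genotypes: every genotype pair
    # except the double heterozygote phases uniquely.
    n_dh = counts[1, 1]
    base = np.zeros(4)  # ab, aB, Ab, AB
    for (ga, gb), cell in np.ndenumerate(counts):
        if cell == 0 or (ga == 1 and gb == 1):
            continue
        # alleles split deterministically: min(g,1)+... enumerate haplotypes
        h1 = (1 if ga >= 1 else 0, 1 if gb >= 1 else 0)
        h2 = (1 if ga == 2 else 0, 1 if gb == 2 else 0)
        for h in (h1, h2):
            base[HAPLOTYPES.index(h)] += cell

    trace = []
    for it in range(1, max_iter + 1):
        f_ab, f_aB, f_Ab, f_AB = freqs
        denom = f_AB * f_ab + f_Ab * f_aB
        w_cis = 0.5 if denom == 0 else f_AB * f_ab / denom  # P(AB/ab | double het)
        hap_counts = base.copy()
        hap_counts[3] += n_dh * w_cis       # AB
        hap_counts[0] += n_dh * w_cis       # ab
        hap_counts[2] += n_dh * (1 - w_cis)  # Ab
        hap_counts[1] += n_dh * (1 - w_cis)  # aB
        new = hap_counts / (2 * n)
        trace.append(two_locus_loglik(counts, new))
        delta = np.max(np.abs(new - freqs))
        freqs = new
        if delta < tol:
            return EmResult(freqs, trace[-1], it, trace)
    raise ConvergenceError(
        f"two-locus EM did not converge in {max_iter} iterations",
        last_state=EmResult(freqs, trace[-1], max_iter, trace))


class DPrimeResult(NamedTuple):
    value: float
    monomorphic: bool


def d_prime(freqs) -> DPrimeResult:
    """|D'| from four haplotype frequencies (order ab, aB, Ab, AB).

    D = f_AB - p_A p_B; D' = D / Dmax with Dmax = min(p_A q_B, q_A p_B)
    for D > 0 and min(p_A p_B, q_A q_B) for D < 0.  Returns 0 with a
    flag when either locus is monomorphic (D' undefined).
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < -1e-12) or abs(f.sum() - 1) > 1e-6:
        raise DataError("freqs must be 4 probabilities summing to 1")
    f_ab, f_aB, f_Ab, f_AB = f
    p_a = f_Ab + f_AB
    p_b = f_aB + f_AB
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        return DPrimeResult(0.0, True)
    d = f_AB - p_a * p_b
    if d > 0:
        dmax = min(p_a * q_b, q_a * p_b)
    else:
        dmax = min(p_a * p_b, q_a * q_b)
    if dmax == 0:
        return DPrimeResult(0.0, True)
    return DPrimeResult(float(min(abs(d / dmax), 1.0)), False)


def ld_report(table: GenotypeTable) -> pd.DataFrame:
    """|D'| for every within-gene SNP pair (pairwise-complete subjects)."""
    rows = []
    info = table.snp_info
    for gene, snps in info.groupby("gene").groups.items():
        snps = [s for s in table.snp_ids if s in set(snps)]
        for a, b in itertools.combinations(snps, 2):
            em = em_haplotype_freqs(table.genotypes[a], table.genotypes[b])
            dp = d_prime(em.freqs)
            rows.append((gene, a, b, dp.value, dp.monomorphic, em.n_iter))
    return pd.DataFrame(rows, columns=["gene", "snp_a", "snp_b", "d_prime",
                                       "monomorphic", "em_iterations"])


@dataclass(frozen=True)
class LdBlock:
    gene: str
    members: tuple
    representative: str | None = None


def find_ld_blocks(table: GenotypeTable, threshold: float = 0.8,
                   pairs: pd.DataFrame | None = None) -> list[LdBlock]:
    """Connected components of the within-gene |D'| > threshold graph.

    SNPs in different genes are never merged; SNPs without a strong
    partner form singleton blocks.  Block member order follows the
    genotype table's column order.
    """
    if pairs is None:
        pairs = ld_report(table)
    order = {s: i for i, s in enumerate(table.snp_ids)}
    blocks = []
    for gene, sub in table.snp_info.groupby("gene", sort=False).groups.items():
        snps = [s for s in table.snp_ids if s in set(sub)]
        g = nx.Graph()
        g.add_nodes_from(snps)
        gene_pairs = pairs[pairs["gene"] == gene]
        for _, row in gene_pairs.iterrows():
            if row["d_prime"] > threshold:
                g.add_edge(row["snp_a"], row["snp_b"])
        for comp in nx.connected_components(g):
            members = tuple(sorted(comp, key=order.get))
            blocks.append(LdBlock(gene=gene, members=members))
    blocks.sort(key=lambda b: order[b.members[0]])
    return blocks


def prune_blocks(candidates: Sequence[str], blocks: Sequence[LdBlock],
                 rule: str = "min_p", pvalues: dict | None = None) -> list[str]:
    """Retain one SNP per LD block among the candidate SNPs.

    ``rule='min_p'`` keeps the candidate with the smallest p-value in
    ``pvalues`` (ties and missing p-values resolve to listed order);
    ``rule='first'`` keeps the first candidate in block order;
    ``rule='other_member'`` keeps the *second* choice of the min_p
    ordering where one exists (the alternative-panel sensitivity rule).
    """
    membership: dict[str, LdBlock] = {}
    for block in blocks:
        for snp in block.members:
            if snp in membership:
                raise DataError(f"SNP {snp} appears in more than one block")
            membership[snp] = block
    missing = [c for c in candidates if c not in membership]
    if missing:
        raise DataError(f"candidates not covered by any block: {missing}")

    pvalues = pvalues or {}
    retained = []
    seen = set()
    for cand in candidates:
        block = membership[cand]
        if id(block) in seen:
            continue
        seen.add(id(block))
        members = [s for s in block.members if s in set(candidates)]
        if rule == "first":
            pick = members[0]
        else:
            ranked = sorted(members,
                            key=lambda s: (pvalues.get(s, np.inf),
                                           block.members.index(s)))
            if rule == "min_p":
                pick = ranked[0]
            elif rule == "other_member":
                pick = ranked[1] if len(ranked) > 1 else ranked[0]
            else:
                raise DataError(f"unknown pruning rule: {rule}")
        retained.append(pick)
    return retained
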