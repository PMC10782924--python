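"""Domain types and file I/O for PGx polygenic-score analysis.

All on-disk formats are plain tab-separated text so they stay interoperable
with standard GWAS tooling.  Effect sizes on disk are on the per-allele scale;
conversion to the standardized scale used by the samplers happens in
:mod:`pgxprs.ld`.

Conventions: coordinates are 1-based (VCF style); ``a1`` is always the effect
allele; variant identity for joining is the id when present on both sides,
otherwise ``(chrom, pos, {a1, a2})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "PGxSummaryStats",
    "DiseaseSummaryStats",
    "LDBlockPanel",
    "LDBlock",
    "PGxCohort",
    "HarmonizeReport",
    "read_pgx_sumstats",
    "write_pgx_sumstats",
    "read_disease_sumstats",
    "write_disease_sumstats",
    "read_ld_panel",
    "write_ld_panel",
    "read_cohort",
    "write_cohort",
    "read_weights",
    "write_weights",
    "harmonize",
]

_VALID_ALLELES = frozenset("ACGT")

PGX_COLUMNS = [
    "SNP", "CHR", "POS", "A1", "A2", "EAF",
    "BETA_G", "SE_G", "P_G", "BETA_GT", "SE_GT", "P_GT", "N", "R_TREATED",
]
DISEASE_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]
WEIGHT_COLUMNS = ["SNP", "CHR", "POS", "A1", "BETA_G_POST", "BETA_GT_POST", "POPULATION"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNP; ``a1`` is the effect allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self):
        if self.a1 == self.a2:
            raise ValidationError(f"{self.id}: effect and other allele identical ({self.a1})")
        for a in (self.a1, self.a2):
            if a not in _VALID_ALLELES:
                raise ValidationError(f"{self.id}: allele {a!r} not a SNP allele")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position {self.pos} < 1")

    @property
    def is_ambiguous(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) pairs."""
        return {self.a1, self.a2} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "VariantKey":
        return replace(self, a1=self.a2, a2=self.a1)


def _check_variants(variants: Sequence[VariantKey]) -> None:
    ids = [v.id for v in variants]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate variant ids: {dup[:5]}")


@dataclass
class PGxSummaryStats:
    """Marginal prognostic (G) and predictive (G×T) summary statistics.

    ``n_G``/``n_GT`` are per-component effective sample sizes; they equal ``n``
    except for Disease+PGx composites where the prognostic component comes
    from a (larger) disease GWAS.
    """

    population: str
    variants: list[VariantKey]
    beta_G: np.ndarray
    se_G: np.ndarray
    p_G: np.ndarray
    beta_GT: np.ndarray
    se_GT: np.ndarray
    p_GT: np.ndarray
    n: int
    treated_fraction: float
    eaf: np.ndarray
    n_G: int | None = None
    n_GT: int | None = None
    # provenance of the prognostic component: "pgx_joint" for the usual
    # per-SNP joint regression on (1, T, g, g·T); "disease_marginal" after a
    # Disease+PGx composite, where beta_G is a single-arm simple-regression
    # estimate and the original PGx prognostic stats are kept alongside for
    # reconstructing the interaction cross-product.
    prognostic_source: str = "pgx_joint"
    beta_G_pgx: np.ndarray | None = None
    se_G_pgx: np.ndarray | None = None

    def __post_init__(self):
        m = len(self.variants)
        _check_variants(self.variants)
        for name in ("beta_G", "se_G", "p_G", "beta_GT", "se_GT", "p_GT", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (m,):
                raise ValidationError(f"{name}: expected length {m}, got {arr.shape}")
        if np.any(self.se_G <= 0) or np.any(self.se_GT <= 0):
            raise ValidationError("standard errors must be strictly positive")
        for p in (self.p_G, self.p_GT):
            if np.any((p <= 0) | (p > 1)):
                raise ValidationError("p-values must lie in (0, 1]")
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        if not (0.0 < self.treated_fraction < 1.0):
            raise ValidationError("treated_fraction must be strictly inside (0, 1)")
        if self.n_G is None:
            self.n_G = self.n
        if self.n_GT is None:
            self.n_GT = self.n
        if self.prognostic_source not in ("pgx_joint", "disease_marginal"):
            raise ValidationError(f"unknown prognostic_source {self.prognostic_source!r}")
        for name in ("beta_G_pgx", "se_G_pgx"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.shape != (m,):
                    raise ValidationError(f"{name}: expected length {m}")

    @property
    def m(self) -> int:
        return len(self.variants)

    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def take(self, idx: np.ndarray) -> "PGxSummaryStats":
        """Row subset/reorder by integer index, preserving metadata."""
        return PGxSummaryStats(
            population=self.population,
            variants=[self.variants[i] for i in idx],
            beta_G=self.beta_G[idx], se_G=self.se_G[idx], p_G=self.p_G[idx],
            beta_GT=self.beta_GT[idx], se_GT=self.se_GT[idx], p_GT=self.p_GT[idx],
            n=self.n, treated_fraction=self.treated_fraction, eaf=self.eaf[idx],
            n_G=self.n_G, n_GT=self.n_GT,
            prognostic_source=self.prognostic_source,
            beta_G_pgx=None if self.beta_G_pgx is None else self.beta_G_pgx[idx],
            se_G_pgx=None if self.se_G_pgx is None else self.se_G_pgx[idx],
        )


@dataclass
class DiseaseSummaryStats:
    """Per-SNP marginal effects from a (single-arm) disease GWAS."""

    variants: list[VariantKey]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: int
    eaf: np.ndarray

    def __post_init__(self):
        m = len(self.variants)
        _check_variants(self.variants)
        for name in ("beta", "se", "p", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (m,):
                raise ValidationError(f"{name}: expected length {m}, got {arr.shape}")
        if np.any(self.se <= 0):
            raise ValidationError("standard errors must be strictly positive")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValidationError("p-values must lie in (0, 1]")
        if self.n < 2:
            raise ValidationError("n must be >= 2")

    @property
    def m(self) -> int:
        return len(self.variants)

    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def take(self, idx: np.ndarray) -> "DiseaseSummaryStats":
        return DiseaseSummaryStats(
            variants=[self.variants[i] for i in idx],
            beta=self.beta[idx], se=self.se[idx], p=self.p[idx],
            n=self.n, eaf=self.eaf[idx],
        )


@dataclass
class LDBlock:
    variant_ids: list[str]
    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.variant_ids)
        if self.R.shape != (m, m):
            raise FormatError(f"LD block matrix shape {self.R.shape} != ({m},{m})")


@dataclass
class LDBlockPanel:
    """Block-diagonal LD reference: per-block SNP lists and correlation matrices."""

    population: str
    blocks: list[LDBlock]
    variants: list[VariantKey] = field(default_factory=list)

    def __post_init__(self):
        all_ids = [i for b in self.blocks for i in b.variant_ids]
        if len(set(all_ids)) != len(all_ids):
            raise ValidationError("variant ids repeat across LD blocks")
        for b in self.blocks:
            R = b.R
            if np.abs(R - R.T).max(initial=0.0) > 1e-8:
                raise ValidationError("LD block matrix not symmetric")
            if np.any(np.abs(R) > 1 + 1e-6):
                raise ValidationError("LD correlation entries must lie in [-1, 1]")
            if len(b.variant_ids) and np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValidationError("LD block matrix not PSD")

    @property
    def m(self) -> int:
        return sum(len(b.variant_ids) for b in self.blocks)

    def ids(self) -> list[str]:
        return [i for b in self.blocks for i in b.variant_ids]

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + len(b.variant_ids)))
            start += len(b.variant_ids)
        return out

    def dense(self) -> np.ndarray:
        """Full m×m block-diagonal correlation matrix (tests/small m only)."""
        from scipy.linalg import block_diag
        return block_diag(*[b.R for b in self.blocks])

    def subset(self, keep_ids: Iterable[str]) -> "LDBlockPanel":
        keep = set(keep_ids)
        blocks = []
        for b in self.blocks:
            idx = [i for i, vid in enumerate(b.variant_ids) if vid in keep]
            if idx:
                blocks.append(LDBlock([b.variant_ids[i] for i in idx],
                                      b.R[np.ix_(idx, idx)]))
        id2v = {v.id: v for v in self.variants}
        variants = [id2v[i] for blk in blocks for i in blk.variant_ids if i in id2v]
        return LDBlockPanel(self.population, blocks, variants)


@dataclass
class PGxCohort:
    """Individual-level randomized-trial data: response, arm, dosages."""

    population: str
    Y: np.ndarray
    T: np.ndarray
    G: np.ndarray
    variants: list[VariantKey]
    sample_ids: list[str] | None = None
    single_arm: bool = False

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.Y)
        if len(self.T) != n or self.G.shape[0] != n:
            raise ValidationError("Y, T and G row counts differ")
        if self.G.shape[1] != len(self.variants):
            raise ValidationError("G column count != number of variants")
        if not np.isin(self.T, (0.0, 1.0)).all():
            raise ValidationError("treatment indicator must be 0/1")
        if not self.single_arm and len(np.unique(self.T)) < 2:
            raise ValidationError("cohort has a single arm but is not flagged single_arm")
        if np.isnan(self.G).any():
            raise ValidationError("missing dosages present; impute or drop before constructing")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def m(self) -> int:
        return self.G.shape[1]

    def ids(self) -> list[str]:
        return [v.id for v in self.variants]


@dataclass
class HarmonizeReport:
    n_input: int
    n_kept: int
    n_flipped: int
    n_dropped_ambiguous: int
    n_dropped_mismatch: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    string_cols = ("SNP", "CHR", "A1", "A2", "FILE", "IID", "POPULATION")
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in string_cols})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    numeric = [c for c in required if c not in string_cols]
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as e:
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric value in column {c} at line {line}") from e
    return df


def _variants_from_frame(df: pd.DataFrame) -> list[VariantKey]:
    return [
        VariantKey(str(r.SNP), str(r.CHR), int(r.POS), str(r.A1).upper(), str(r.A2).upper())
        for r in df.itertuples()
    ]


def read_pgx_sumstats(path, population: str = "POP1") -> PGxSummaryStats:
    """Read a PGx summary-statistics TSV (columns :data:`PGX_COLUMNS`)."""
    df = _read_table(path, PGX_COLUMNS)
    n = int(df["N"].iloc[0])
    r = float(df["R_TREATED"].iloc[0])
    return PGxSummaryStats(
        population=population,
        variants=_variants_from_frame(df),
        beta_G=df["BETA_G"].to_numpy(), se_G=df["SE_G"].to_numpy(), p_G=df["P_G"].to_numpy(),
        beta_GT=df["BETA_GT"].to_numpy(), se_GT=df["SE_GT"].to_numpy(), p_GT=df["P_GT"].to_numpy(),
        n=n, treated_fraction=r, eaf=df["EAF"].to_numpy(),
    )


def write_pgx_sumstats(ss: PGxSummaryStats, path) -> None:
    df = pd.DataFrame({
        "SNP": ss.ids(),
        "CHR": [v.chrom for v in ss.variants],
        "POS": [v.pos for v in ss.variants],
        "A1": [v.a1 for v in ss.variants],
        "A2": [v.a2 for v in ss.variants],
        "EAF": ss.eaf,
        "BETA_G": ss.beta_G, "SE_G": ss.se_G, "P_G": ss.p_G,
        "BETA_GT": ss.beta_GT, "SE_GT": ss.se_GT, "P_GT": ss.p_GT,
        "N": ss.n, "R_TREATED": ss.treated_fraction,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_disease_sumstats(path) -> DiseaseSummaryStats:
    df = _read_table(path, DISEASE_COLUMNS)
    return DiseaseSummaryStats(
        variants=_variants_from_frame(df),
        beta=df["BETA"].to_numpy(), se=df["SE"].to_numpy(), p=df["P"].to_numpy(),
        n=int(df["N"].iloc[0]), eaf=df["EAF"].to_numpy(),
    )


def write_disease_sumstats(ss: DiseaseSummaryStats, path) -> None:
    df = pd.DataFrame({
        "SNP": ss.ids(),
        "CHR": [v.chrom for v in ss.variants],
        "POS": [v.pos for v in ss.variants],
        "A1": [v.a1 for v in ss.variants],
        "A2": [v.a2 for v in ss.variants],
        "EAF": ss.eaf, "BETA": ss.beta, "SE": ss.se, "P": ss.p, "N": ss.n,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ld_panel(manifest_path, population: str = "POP1") -> LDBlockPanel:
    """Read a block-structured LD panel.

    The manifest is a TSV ``BLOCK_ID FILE N_SNPS``; each ``FILE`` stem names a
    whitespace-delimited square matrix file and a ``<stem>.snps.tsv`` manifest
    (``SNP CHR POS A1 A2``).  Symmetry is enforced by averaging with the
    transpose and the diagonal is reset to exactly 1.
    """
    manifest_path = Path(manifest_path)
    man = _read_table(manifest_path, ["BLOCK_ID", "FILE", "N_SNPS"])
    blocks, variants = [], []
    for row in man.itertuples():
        mat_path = manifest_path.parent / str(row.FILE)
        R = np.loadtxt(mat_path, ndmin=2)
        if R.shape[0] != R.shape[1]:
            raise FormatError(f"{mat_path}: LD matrix not square ({R.shape})")
        if np.any(np.abs(R) > 1 + 1e-6):
            raise ValidationError(f"{mat_path}: correlation entry outside [-1, 1]")
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        snp_df = _read_table(mat_path.with_suffix("").parent / (mat_path.name + ".snps.tsv"),
                             ["SNP", "CHR", "POS", "A1", "A2"])
        if len(snp_df) != R.shape[0]:
            raise FormatError(f"{mat_path}: SNP list length {len(snp_df)} != matrix dim {R.shape[0]}")
        vs = _variants_from_frame(snp_df)
        blocks.append(LDBlock([v.id for v in vs], R))
        variants.extend(vs)
    return LDBlockPanel(population, blocks, variants)


def write_ld_panel(panel: LDBlockPanel, manifest_path) -> None:
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    id2v = {v.id: v for v in panel.variants}
    for i, b in enumerate(panel.blocks):
        fname = f"{manifest_path.stem}_block{i}.txt"
        np.savetxt(manifest_path.parent / fname, b.R, fmt="%.17g")
        vs = [id2v[x] for x in b.variant_ids]
        pd.DataFrame({
            "SNP": [v.id for v in vs], "CHR": [v.chrom for v in vs],
            "POS": [v.pos for v in vs], "A1": [v.a1 for v in vs], "A2": [v.a2 for v in vs],
        }).to_csv(manifest_path.parent / (fname + ".snps.tsv"), sep="\t", index=False)
        rows.append({"BLOCK_ID": i, "FILE": fname, "N_SNPS": len(b.variant_ids)})
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def _dosage_from_vcf(geno_path, variants: list[VariantKey]) -> tuple[np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(geno_path))
    samples = list(vcf.samples)
    want = {(v.chrom, v.pos): v for v in variants}
    cols = {v.id: None for v in variants}
    for rec in vcf:
        key = (str(rec.CHROM), int(rec.POS))
        v = want.get(key)
        if v is None:
            continue
        alt = rec.ALT[0] if rec.ALT else None
        # gt_types not used: count effect-allele copies explicitly
        gts = rec.genotypes  # [a, b, phased]
        alt_dosage = np.array([max(g[0], 0) + max(g[1], 0) for g in gts], dtype=float)
        if v.a1 == alt and v.a2 == rec.REF:
            cols[v.id] = alt_dosage
        elif v.a1 == rec.REF and v.a2 == alt:
            cols[v.id] = 2.0 - alt_dosage
        # irreconcilable alleles: leave missing -> error below
    missing = [k for k, c in cols.items() if c is None]
    if missing:
        raise ValidationError(f"variants absent or allele-incompatible in VCF: {missing[:5]}")
    G = np.column_stack([cols[v.id] for v in variants])
    return G, samples


def read_cohort(pheno_path, geno_path, variant_manifest=None,
                population: str = "POP1") -> PGxCohort:
    """Load a trial cohort from a phenotype TSV plus dosage TSV or VCF.

    Phenotype file has columns ``IID Y T``.  A dosage TSV has ``IID`` followed
    by one column per SNP id; a VCF requires ``variant_manifest`` (TSV
    ``SNP CHR POS A1 A2``) naming the SNPs and their effect alleles.  Samples
    are matched on ``IID``; zero overlap is an error.
    """
    ph = _read_table(pheno_path, ["IID", "Y", "T"])
    ph["IID"] = ph["IID"].astype(str)
    geno_path = Path(geno_path)
    if geno_path.suffix in (".vcf", ".gz") or geno_path.name.endswith(".vcf.gz"):
        if variant_manifest is None:
            raise FormatError("VCF genotype input requires a variant manifest")
        vdf = _read_table(variant_manifest, ["SNP", "CHR", "POS", "A1", "A2"])
        variants = _variants_from_frame(vdf)
        G_all, samples = _dosage_from_vcf(geno_path, variants)
        gdf = pd.DataFrame(G_all, index=[str(s) for s in samples],
                           columns=[v.id for v in variants])
    else:
        gdf = pd.read_csv(geno_path, sep="\t", dtype={"IID": str})
        if "IID" not in gdf.columns:
            raise FormatError(f"{geno_path}: missing required column(s) ['IID']")
        gdf = gdf.set_index("IID")
        if variant_manifest is not None:
            vdf = _read_table(variant_manifest, ["SNP", "CHR", "POS", "A1", "A2"])
            variants = _variants_from_frame(vdf)
        else:
            variants = [VariantKey(c, "0", i + 1, "A", "G")
                        for i, c in enumerate(gdf.columns)]
    common = [i for i in ph["IID"] if i in gdf.index]
    if not common:
        raise ValidationError("no overlapping samples between phenotype and genotype files")
    ph = ph.set_index("IID").loc[common]
    G = gdf.loc[common, [v.id for v in variants]].to_numpy(dtype=float)
    return PGxCohort(population=population, Y=ph["Y"].to_numpy(),
                     T=ph["T"].to_numpy(), G=G, variants=variants,
                     sample_ids=list(common))


def write_cohort(cohort: PGxCohort, pheno_path, geno_path) -> None:
    iids = cohort.sample_ids or [f"S{i}" for i in range(cohort.n)]
    pd.DataFrame({"IID": iids, "Y": cohort.Y, "T": cohort.T.astype(int)}).to_csv(
        pheno_path, sep="\t", index=False, float_format="%.17g")
    gdf = pd.DataFrame(cohort.G, columns=cohort.ids())
    gdf.insert(0, "IID", iids)
    gdf.to_csv(geno_path, sep="\t", index=False, float_format="%.17g")


def write_weights(weights: pd.DataFrame, path) -> None:
    """Write an effect-weight table (columns :data:`WEIGHT_COLUMNS`)."""
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise FormatError(f"weight table missing column(s) {missing}")
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path) -> pd.DataFrame:
    return _read_table(path, WEIGHT_COLUMNS)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _match_orientation(v: VariantKey, ref: VariantKey) -> int | None:
    """+1 if alleles match the reference orientation, -1 if swapped, None otherwise."""
    if (v.a1, v.a2) == (ref.a1, ref.a2):
        return 1
    if (v.a1, v.a2) == (ref.a2, ref.a1):
        return -1
    comp = str.maketrans("ACGT", "TGCA")
    fa1, fa2 = v.a1.translate(comp), v.a2.translate(comp)
    if (fa1, fa2) == (ref.a1, ref.a2):
        return 1
    if (fa1, fa2) == (ref.a2, ref.a1):
        return -1
    return None


def harmonize(sumstats, panel: LDBlockPanel, cohort: PGxCohort | None = None,
              drop_ambiguous: bool = True):
    """Restrict sumstats/panel/cohort to shared variants in panel order.

    Allele orientation follows the panel.  Swapped-allele sumstats rows get
    their effect signs flipped and ``eaf`` replaced by ``1 - eaf``;
    strand-ambiguous SNPs (A/T, C/G) are dropped when ``drop_ambiguous``;
    variants whose alleles cannot be reconciled are dropped and counted.

    Returns ``(sumstats, panel, cohort, HarmonizeReport)``.
    """
    panel_vs = {v.id: v for v in panel.variants}
    panel_pos = {(v.chrom, v.pos): v for v in panel.variants}
    ss_index: dict[str, int] = {}
    for i, v in enumerate(sumstats.variants):
        ref = panel_vs.get(v.id) or panel_pos.get((v.chrom, v.pos))
        if ref is not None:
            ss_index[ref.id] = i

    cohort_index = None
    if cohort is not None:
        cid = {v.id: j for j, v in enumerate(cohort.variants)}
        cohort_index = {pid: cid[pid] for pid in ss_index if pid in cid}

    kept_ids, flips = [], []
    n_flip = n_amb = n_bad = 0
    for pid in panel.ids():
        if pid not in ss_index:
            continue
        if cohort_index is not None and pid not in cohort_index:
            continue
        v = sumstats.variants[ss_index[pid]]
        ref = panel_vs[pid]
        if drop_ambiguous and ref.is_ambiguous:
            n_amb += 1
            continue
        sign = _match_orientation(v, ref)
        if sign is None:
            n_bad += 1
            continue
        kept_ids.append(pid)
        flips.append(sign)
        if sign < 0:
            n_flip += 1
    if not kept_ids:
        raise ValidationError("no variants shared between sumstats, panel"
                              + ("" if cohort is None else " and cohort"))

    idx = np.array([ss_index[p] for p in kept_ids])
    signs = np.array(flips, dtype=float)
    ss2 = sumstats.take(idx)
    # re-orient to the panel's alleles
    ss2.variants = [panel_vs[p] for p in kept_ids]
    if isinstance(ss2, PGxSummaryStats):
        ss2.beta_G = ss2.beta_G * signs
        ss2.beta_GT = ss2.beta_GT * signs
        if ss2.beta_G_pgx is not None:
            ss2.beta_G_pgx = ss2.beta_G_pgx * signs
    else:
        ss2.beta = ss2.beta * signs
    ss2.eaf = np.where(signs < 0, 1.0 - ss2.eaf, ss2.eaf)

    panel2 = panel.subset(kept_ids)

    cohort2 = None
    if cohort is not None:
        cvs = {v.id: v for v in cohort.variants}
        cidx = np.array([cohort_index[p] for p in kept_ids])
        Gsub = cohort.G[:, cidx].copy()
        for j, pid in enumerate(kept_ids):
            csign = _match_orientation(cvs[pid], panel_vs[pid])
            if csign is not None and csign < 0:
                Gsub[:, j] = 2.0 - Gsub[:, j]
        cohort2 = PGxCohort(cohort.population, cohort.Y, cohort.T, Gsub,
                            [panel_vs[p] for p in kept_ids],
                            sample_ids=cohort.sample_ids, single_arm=cohort.single_arm)

    report = HarmonizeReport(n_input=sumstats.m, n_kept=len(kept_ids),
                             n_flipped=n_flip, n_dropped_ambiguous=n_amb,
                             n_dropped_mismatch=n_bad)
    return ss2, panel2, cohort2, report
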