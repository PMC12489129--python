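"""Synthetic myogenesis time-course data with planted truth.

Emulates the study design the pipeline targets: two myoblast cell lines
sampled daily over a 5-day differentiation (days 0-5), three replicates per
condition (36 samples), negative-binomial isoform counts driven by gene-level
temporal programs in five canonical shapes, within-gene isoform-proportion
switches, a log2 cell-line offset, and log-normal library-size variation.

Every generator is a pure function of its seed so downstream recovery tests
can compare against the planted truth bitwise-reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, JunctionCatalog, TranscriptModel

# Canonical temporal programs as log2 fold-change trajectories over days 0-5,
# expressed on a unit scale (max |log2FC| = 1) and scaled by an amplitude.
#   Down       : declining linearly up to day 3, then stable
#   EarlyDown  : dramatic decline on the first day, then stable
#   EarlyUp    : immediate increase, then stable
#   Up         : increasing linearly up to day 3, then stable
#   UpDown     : initial increase followed by a late decrease
# "Mix" has no deterministic template; it is drawn as a random walk.
SHAPE_TEMPLATES: dict[str, np.ndarray] = {
    "Down": np.array([0.0, -1 / 3, -2 / 3, -1.0, -1.0, -1.0]),
    "EarlyDown": np.array([0.0, -1.0, -1.0, -1.0, -1.0, -1.0]),
    "EarlyUp": np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
    "Up": np.array([0.0, 1 / 3, 2 / 3, 1.0, 1.0, 1.0]),
    "UpDown": np.array([0.0, 0.8, 0.8, 0.0, -0.4, -0.8]),
}

GENE_CLUSTER_LABELS = ("Down", "EarlyDown", "EarlyUp", "Up", "Mix")
ISOFORM_CLUSTER_LABELS = ("Down", "UpDown", "EarlyUp", "Up", "Mix")


@dataclass(frozen=True)
class DesignSpec:
    """Sample layout of the time course.

    Defaults reproduce the study layout: 2 cell lines x 6 daily time points
    x 3 replicates = 36 samples, which also makes the usage-filter sample
    thresholds (18 = half the samples) meaningful.
    """

    n_cell_lines: int = 2
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    replicates_per_condition: int = 3
    library_size_mean: float = 1e6
    library_size_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1 or self.replicates_per_condition < 1:
            raise ValueError("design needs >=1 cell line and >=1 replicate")
        if len(self.days) < 2:
            raise ValueError("design needs >=2 days")

    @property
    def n_samples(self) -> int:
        return self.n_cell_lines * len(self.days) * self.replicates_per_condition

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_cell_lines):
            for d in self.days:
                for r in range(self.replicates_per_condition):
                    rows.append(
                        {
                            "sample_id": f"line{c + 1}_day{d}_rep{r + 1}",
                            "cell_line": f"line{c + 1}",
                            "day": d,
                            "replicate": r + 1,
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


def shape_trajectory(label: str, days: tuple[int, ...], amplitude: float,
                     rng: np.random.Generator | None = None,
                     mix_step_sd: float = 0.5) -> np.ndarray:
    """log2 fold-change trajectory (relative to day 0) for a cluster label.

    Mix trajectories are random walks with no planted trend and require an
    ``rng``; all other labels are deterministic template * amplitude.
    """
    if label == "Mix":
        if rng is None:
            raise ValueError("Mix trajectories require an rng")
        steps = rng.normal(0.0, mix_step_sd * amplitude, size=len(days) - 1)
        return np.concatenate([[0.0], np.cumsum(steps)])
    if label not in SHAPE_TEMPLATES:
        raise ValueError(f"unknown cluster shape {label!r}")
    template = SHAPE_TEMPLATES[label]
    if len(days) != len(template):
        raise ValueError("shape templates are defined for 6 days")
    return amplitude * template


@dataclass
class TruthBundle:
    """Planted simulation truth for one synthetic dataset."""

    gene_ids: list[str]
    isoform_ids: list[str]
    iso_gene: pd.Series                 # isoform -> gene
    cluster_label: pd.Series            # per gene
    trajectories: pd.DataFrame          # gene x day, log2FC vs day 0
    dtu_flag: pd.Series                 # per gene, bool
    pi0: pd.Series                      # per isoform, baseline proportion
    pi1: pd.Series                      # per isoform, switched proportion
    mu: pd.Series                       # per gene baseline mean at nominal depth
    alpha: pd.Series                    # per gene NB dispersion
    delta: pd.Series                    # per gene log2 cell-line offset
    gamma: float | None                 # Dirichlet-multinomial precision, None = no extra noise
    seed: int

    def __post_init__(self) -> None:
        if (self.mu <= 0).any():
            raise ValueError("baseline means must be positive")
        if (self.alpha < 0).any():
            raise ValueError("NB dispersions must be nonnegative")
        for pi in (self.pi0, self.pi1):
            if ((pi < 0) | (pi > 1)).any():
                raise ValueError("proportions must lie in [0, 1]")
            sums = pi.groupby(self.iso_gene).sum()
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError("per-gene proportions must sum to 1")

    def proportions_at(self, day: int, switch_day: int = 3) -> pd.Series:
        """Planted isoform proportions at a day: linear pi0 -> pi1 over days
        0..switch_day for DTU genes, constant afterwards and for non-DTU genes."""
        frac = min(day, switch_day) / switch_day
        pi = self.pi0.copy()
        dtu_iso = self.iso_gene.map(self.dtu_flag).astype(bool)
        pi[dtu_iso] = (1 - frac) * self.pi0[dtu_iso] + frac * self.pi1[dtu_iso]
        return pi


def make_truth(
    design: DesignSpec,
    n_genes: int,
    seed: int,
    isoforms_per_gene: int | tuple[int, ...] = 1,
    cluster_labels: tuple[str, ...] | None = None,
    de_fraction: float = 1.0,
    amplitude: float = 3.0,
    dtu_fraction: float = 0.0,
    dtu_swap: float = 0.4,
    mu_log_mean: float = np.log(300.0),
    mu_log_sd: float = 0.5,
    alpha: float = 0.05,
    delta_sd: float = 0.25,
    gamma: float | None = None,
) -> TruthBundle:
    """Draw a :class:`TruthBundle` with planted temporal programs and switches.

    ``de_fraction`` of genes receive a cluster trajectory (labels cycled from
    ``cluster_labels``); the rest are flat ("none").  ``dtu_fraction`` of
    multi-isoform genes receive a proportion switch of total variation
    ``dtu_swap`` between day 0 and day 3.
    """
    rng = np.random.default_rng(seed)
    if cluster_labels is None:
        cluster_labels = GENE_CLUSTER_LABELS
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    if isinstance(isoforms_per_gene, int):
        n_iso = np.full(n_genes, isoforms_per_gene)
    else:
        n_iso = np.asarray(isoforms_per_gene)
        if len(n_iso) != n_genes:
            raise ValueError("isoforms_per_gene length must equal n_genes")

    iso_ids, iso_gene = [], []
    for g, gid in enumerate(gene_ids):
        for k in range(n_iso[g]):
            iso_ids.append(f"{gid}.t{k + 1}")
            iso_gene.append(gid)
    iso_gene = pd.Series(iso_gene, index=iso_ids, name="gene_id")

    n_de = int(round(de_fraction * n_genes))
    labels = ["none"] * n_genes
    for i in range(n_de):
        labels[i] = cluster_labels[i % len(cluster_labels)]
    cluster_label = pd.Series(labels, index=gene_ids, name="cluster")

    traj = np.zeros((n_genes, len(design.days)))
    for g, lab in enumerate(labels):
        if lab == "none":
            continue
        traj[g] = shape_trajectory(lab, design.days, amplitude, rng=rng)
    trajectories = pd.DataFrame(traj, index=gene_ids, columns=list(design.days))

    multi = n_iso >= 2
    dtu = np.zeros(n_genes, dtype=bool)
    eligible = np.flatnonzero(multi)
    n_dtu = int(round(dtu_fraction * len(eligible)))
    if n_dtu:
        dtu[rng.choice(eligible, size=n_dtu, replace=False)] = True
    dtu_flag = pd.Series(dtu, index=gene_ids, name="dtu")

    pi0 = np.empty(len(iso_ids))
    pi1 = np.empty(len(iso_ids))
    pos = 0
    for g in range(n_genes):
        k = n_iso[g]
        if k == 1:
            p0 = p1 = np.array([1.0])
        else:
            base = rng.dirichlet(np.full(k, 5.0))
            # keep room for the planted swap between the two major isoforms
            lo, hi = dtu_swap / 2 + 0.05, 1 - dtu_swap / 2 - 0.05
            base = np.clip(base, 0.05, None)
            base /= base.sum()
            p0 = base.copy()
            p1 = base.copy()
            if dtu[g]:
                i, j = np.argsort(base)[-2:]
                mid = (base[i] + base[j]) / 2
                p0[i], p0[j] = mid + dtu_swap / 2, mid - dtu_swap / 2
                p1[i], p1[j] = mid - dtu_swap / 2, mid + dtu_swap / 2
                p0 = np.clip(p0, 1e-6, None)
                p1 = np.clip(p1, 1e-6, None)
                p0, p1 = p0 / p0.sum(), p1 / p1.sum()
        pi0[pos : pos + k] = p0
        pi1[pos : pos + k] = p1
        pos += k

    mu = pd.Series(
        rng.lognormal(mu_log_mean, mu_log_sd, size=n_genes), index=gene_ids
    )
    alpha_s = pd.Series(np.full(n_genes, float(alpha)), index=gene_ids)
    delta = pd.Series(rng.normal(0.0, delta_sd, size=n_genes), index=gene_ids)

    return TruthBundle(
        gene_ids=gene_ids,
        isoform_ids=iso_ids,
        iso_gene=iso_gene,
        cluster_label=cluster_label,
        trajectories=trajectories,
        dtu_flag=dtu_flag,
        pi0=pd.Series(pi0, index=iso_ids),
        pi1=pd.Series(pi1, index=iso_ids),
        mu=mu,
        alpha=alpha_s,
        delta=delta,
        gamma=gamma,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2; alpha == 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = alpha[~pois]
        m = mean[~pois]
        n = 1.0 / a
        p = n / (n + m)
        out[~pois] = rng.negative_binomial(n, p)
    return out


def simulate_counts(design: DesignSpec, truth: TruthBundle) -> CountMatrix:
    """Simulate an isoform x sample count matrix from planted truth.

    The expected isoform count in condition (day t, cell line c) is

        (library_size_s / library_size_mean) * mu_g * 2**(traj_g(t) + delta_g*[c==line2]) * pi_i(t)

    With ``truth.gamma`` unset, each isoform is an independent NB draw with
    the gene's dispersion.  With a finite gamma, the gene total is NB and is
    split Dirichlet-multinomially with concentration gamma * pi(t), planting
    replicate-level proportion overdispersion for the usage analysis.
    """
    rng = np.random.default_rng(truth.seed + 1)
    meta = design.sample_table()
    lib_sd = np.sqrt(np.log(1 + design.library_size_cv**2))
    lib_mu = np.log(design.library_size_mean) - lib_sd**2 / 2
    lib = rng.lognormal(lib_mu, lib_sd, size=len(meta))
    lib_sizes = pd.Series(lib, index=meta.index)

    iso_gene = truth.iso_gene
    gene_index = pd.Index(truth.gene_ids)
    day_cols = list(design.days)
    counts = np.zeros((len(truth.isoform_ids), len(meta)), dtype=np.int64)
    iso_pos = {g: np.flatnonzero(iso_gene.to_numpy() == g) for g in truth.gene_ids}

    mu = truth.mu.to_numpy()
    alpha = truth.alpha.to_numpy()
    delta = truth.delta.to_numpy()
    traj = truth.trajectories

    pi_by_day = {d: truth.proportions_at(d).to_numpy() for d in day_cols}

    for j, (sid, row) in enumerate(meta.iterrows()):
        t, c = row["day"], row["cell_line"]
        scale = lib[j] / design.library_size_mean
        shift = traj[t].to_numpy() + (delta if c != "line1" else 0.0)
        gene_mean = scale * mu * np.power(2.0, shift)
        pi = pi_by_day[t]
        if truth.gamma is None:
            for g_i, g in enumerate(gene_index):
                pos = iso_pos[g]
                counts[pos, j] = _nb_draw(
                    rng, gene_mean[g_i] * pi[pos], np.full(len(pos), alpha[g_i])
                )
        else:
            totals = _nb_draw(rng, gene_mean, alpha)
            for g_i, g in enumerate(gene_index):
                pos = iso_pos[g]
                if len(pos) == 1:
                    counts[pos, j] = totals[g_i]
                    continue
                p = rng.dirichlet(truth.gamma * pi[pos])
                counts[pos, j] = rng.multinomial(totals[g_i], p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=truth.isoform_ids, columns=meta.index),
        meta,
        lib_sizes,
    )
    return cm


# ---------------------------------------------------------------------------
# Annotation fixtures for structural classification
# ---------------------------------------------------------------------------


@dataclass
class AnnotationBundle:
    """Synthetic transcript models with per-transcript structural truth."""

    transcripts: list[TranscriptModel]
    reference: list[TranscriptModel]
    catalog: JunctionCatalog
    t2g: pd.Series
    truth_category: pd.Series   # FSM / NIC / NNC per query transcript


def simulate_annotation(
    n_genes: int,
    isoform_count_law: dict[int, float] | None = None,
    novel_fraction: float = 0.0,
    seed: int = 0,
) -> AnnotationBundle:
    """Generate transcript models plus a reference junction catalog.

    Each gene has a multi-exon backbone.  Non-novel transcripts define the
    reference catalog (full backbone or single-exon skips).  Novel
    transcripts alternate between 5' truncations of the backbone (all
    junctions cataloged -> NIC) and double-exon skips that create one novel
    junction (-> NNC); genes whose transcripts are all novel yield NNC only.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if not 0.0 <= novel_fraction <= 1.0:
        raise ValueError("novel_fraction must lie in [0, 1]")
    law = isoform_count_law or {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.15, 5: 0.05}
    ks, ps = zip(*sorted(law.items()))
    if any(k < 1 or k > 5 for k in ks) or abs(sum(ps) - 1) > 1e-9:
        raise ValueError("isoform_count_law must be a distribution over 1..5")

    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    reference: list[TranscriptModel] = []
    t2g_idx, t2g_val, truth = [], [], {}

    for g in range(n_genes):
        gid = f"G{g:05d}"
        n_tx = int(rng.choice(ks, p=ps))
        novel = rng.random(n_tx) < novel_fraction
        n_exons = n_tx + 4  # room for distinct skips/truncations
        base = 100_000 * (g + 1)
        backbone = [
            (base + i * 1000, base + i * 1000 + 199) for i in range(n_exons)
        ]
        strand = "+" if rng.random() < 0.5 else "-"

        n_ref_seen = 0
        nic_next = True
        nic_used = 0
        nnc_used = 0
        gene_has_ref = (~novel).any()
        for k in range(n_tx):
            tid = f"{gid}.t{k + 1}"
            if not novel[k]:
                if n_ref_seen == 0:
                    exons = tuple(backbone)  # full backbone
                else:
                    skip = n_ref_seen  # skip exon index 1, 2, ...
                    exons = tuple(
                        e for i, e in enumerate(backbone) if i != skip
                    )
                n_ref_seen += 1
                cat = "FSM"
            else:
                if gene_has_ref and nic_next:
                    nic_used += 1
                    exons = tuple(backbone[nic_used:])  # 5' truncation
                    cat = "NIC"
                    nic_next = False
                else:
                    nnc_used += 1
                    lo = 2 * nnc_used - 1
                    exons = tuple(
                        e for i, e in enumerate(backbone) if i not in (lo, lo + 1)
                    )
                    cat = "NNC"
                    nic_next = True
            tx = TranscriptModel(tid, gid, "chr1", strand, exons)
            transcripts.append(tx)
            if cat == "FSM":
                reference.append(tx)
            t2g_idx.append(tid)
            t2g_val.append(gid)
            truth[tid] = cat

    catalog = JunctionCatalog.from_transcripts(reference)
    return AnnotationBundle(
        transcripts=transcripts,
        reference=reference,
        catalog=catalog,
        t2g=pd.Series(t2g_val, index=t2g_idx, name="gene_id"),
        truth_category=pd.Series(truth, name="category"),
    )


# ---------------------------------------------------------------------------
# Confidence-score fixtures (coding triage + interaction network)
# ---------------------------------------------------------------------------


def simulate_confidence_tables(
    isoform_ids: list[str],
    known_fraction: float = 0.3,
    high_conf_fraction: float = 0.5,
    seed: int = 0,
    n_proteins: int = 12,
    planted_components: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4)),
    iptm_high: float = 0.9,
    iptm_low: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isoform ORF/pLDDT table and a symmetric pairwise iPTM table.

    pLDDT values for planted high-confidence isoforms are drawn above 0.75,
    low-confidence ones below 0.65, so the 0.7 triage threshold separates
    them exactly.  The iPTM table plants disjoint cliques at ``iptm_high``
    over an ``iptm_low`` background (self-pairs of clique members are high,
    marking homodimers).
    """
    for frac in (known_fraction, high_conf_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(isoform_ids)
    known = rng.random(n) < known_fraction
    high = rng.random(n) < high_conf_fraction
    plddt = np.where(
        high, rng.uniform(0.75, 0.95, n), rng.uniform(0.3, 0.65, n)
    )
    iso_table = pd.DataFrame(
        {
            "has_orf": True,
            "orf_matches_known": known,
            "mean_plddt": plddt,
            "planted_high": high,
        },
        index=pd.Index(isoform_ids, name="transcript_id"),
    )

    prot = [f"P{i:02d}" for i in range(n_proteins)]
    iptm = np.full((n_proteins, n_proteins), iptm_low)
    for comp in planted_components:
        for a in comp:
            for b in comp:
                iptm[a, b] = iptm_high
    iptm = (iptm + iptm.T) / 2
    iptm_df = pd.DataFrame(iptm, index=prot, columns=prot)
    return iso_table, iptm_df


def simulate_profiles(
    labels: list[str],
    amplitude: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Directly simulate z-scale temporal profiles for clustering tests.

    Each profile is the z-scored canonical template scaled to ``amplitude``
    z-units plus iid Gaussian noise; Mix labels get random walks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lab in labels:
        traj = shape_trajectory(lab, days, 1.0, rng=rng)
        sd = traj.std(ddof=1)
        z = (traj - traj.mean()) / (sd if sd > 0 else 1.0)
        rows.append(amplitude * z + rng.normal(0, noise_sd, len(days)))
    return pd.DataFrame(
        rows,
        index=[f"F{i:05d}" for i in range(len(labels))],
        columns=list(days),
    )
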