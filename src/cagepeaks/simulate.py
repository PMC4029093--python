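"""Synthetic CAGE replicate data with planted multi-scale peak architecture.

Each promoter is a broad region (50-200 bp) of transcription initiation
containing one to five narrow sub-peaks (1-10 bp) plus sparse broad
background sites — the laminar structure real CAGE promoters show. Tag
counts per site are negative binomial via Gamma-Poisson mixing; a
promoter-level log-normal intensity factor shared by all samples makes
replicate peak scores concordant while keeping within-condition replicate
noise honest NB. A configurable fraction of promoters is replicate-specific
(emitted in only one sample — spurious peaks that replicate merging must
discard) and independent uniform background noise sites are sprinkled per
replicate.

Differential expression is planted two ways:

* whole-promoter: every site's mean is scaled by the fold change in
  condition 2 (up or down);
* sub-peak shift: two sub-peaks swap intensity shares between conditions so
  each changes by the fold while the promoter total stays constant — the
  pattern where fine-scale TSS usage moves although the gene's overall
  output does not.

Ground truth (promoter intervals, sub-peak intervals, per-interval true
log2 fold changes, reproducibility flags, per-site means, gene TSS table)
is returned alongside the CTSS tables so every pipeline stage can be scored.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ctss import CTSS_COLUMNS, CTSSTable


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulator. Defaults describe a small but
    realistic two-condition CAGE experiment with duplicate libraries."""

    genome_length: int = 600_000
    chrom: str = "chr1"
    n_promoters: int = 60
    broad_width: tuple[int, int] = (50, 200)
    n_subpeaks: tuple[int, int] = (1, 5)
    subpeak_width: tuple[int, int] = (1, 10)
    intensity_scale: float = 300.0   # mean tags per promoter per library
    intensity_sigma: float = 0.7     # log-normal spread of promoter factors
    background_fraction: float = 0.2  # promoter tags outside sub-peaks
    background_step: int = 5         # bp between broad background sites
    dispersion: float = 0.1          # NB dispersion phi of per-site counts
    irreproducible_fraction: float = 0.15
    irreproducible_intensity_factor: float = 0.1   # spurious peaks are weak
    noise_rate: float = 1e-4         # background noise sites per bp per library
    noise_mean: float = 1.5
    frac_whole_de: float = 0.15
    frac_shift_de: float = 0.15
    fold_change: float = 8.0
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("cond1", "cond2")
    share_replicate_streams: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("irreproducible_fraction", "frac_whole_de", "frac_shift_de",
                     "background_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_whole_de + self.frac_shift_de > 1:
            raise ValueError("DE fractions sum to more than 1")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.subpeak_width[1] * self.n_subpeaks[1] > self.broad_width[0]:
            # sub-peaks are placed in equal sub-slots of the broad region;
            # the narrowest broad region must fit the widest architecture
            raise ValueError("sub-peaks cannot fit strictly inside the broad peak")


@dataclasses.dataclass
class SimTruth:
    """Planted ground truth: promoter and sub-peak intervals are half-open,
    laminar by construction; ``site_means`` holds the per-condition expected
    count at every planted site."""

    promoters: pd.DataFrame
    subpeaks: pd.DataFrame
    site_means: pd.DataFrame
    gene_tss: pd.DataFrame


@dataclasses.dataclass
class SimResult:
    tables: dict[str, list[CTSSTable]]
    truth: SimTruth
    config: SimConfig


def _nb_counts(rng: np.random.Generator, means: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, Var = mean + phi mean^2) via Gamma-Poisson mixing."""
    if phi <= 0:
        return rng.poisson(means)
    g = rng.gamma(1.0 / phi, phi, size=means.shape)
    return rng.poisson(g * means)


def simulate_ctss(config: SimConfig | None = None) -> SimResult:
    """Generate replicate CTSS tables for every condition plus ground truth.

    Deterministic given ``config.seed``: promoter architecture comes from a
    master stream and each (condition, replicate) sample from its own
    spawned substream.
    """
    cfg = config or SimConfig()
    cfg.validate()
    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    n = cfg.n_promoters
    n_irrep = int(round(cfg.irreproducible_fraction * n))
    slot = cfg.genome_length // max(n, 1)
    if slot < cfg.broad_width[1] + 2:
        raise ValueError("genome too short for the requested promoter count")

    promoters = []
    subpeak_rows = []
    for p in range(n):
        width = int(master.integers(cfg.broad_width[0], cfg.broad_width[1] + 1))
        start = p * slot + int(master.integers(0, slot - width))
        strand = "+" if master.random() < 0.5 else "-"
        k = int(master.integers(cfg.n_subpeaks[0], cfg.n_subpeaks[1] + 1))
        intensity = cfg.intensity_scale * float(
            np.exp(master.normal(0.0, cfg.intensity_sigma))
        )
        # sub-peaks strictly inside the broad region, one per equal sub-slot
        sub_slot = width // k
        shares = master.dirichlet(np.ones(k)) * (1 - cfg.background_fraction)
        for si in range(k):
            w = int(master.integers(cfg.subpeak_width[0], cfg.subpeak_width[1] + 1))
            w = min(w, max(sub_slot - 2, 1))
            off = int(master.integers(1, max(sub_slot - w, 1) + 1)) if sub_slot - w > 0 else 0
            s = start + si * sub_slot + off
            subpeak_rows.append((p, s, s + w, float(shares[si])))
        promoters.append((p, cfg.chrom, strand, start, start + width, intensity, k))

    prom = pd.DataFrame(
        promoters,
        columns=["promoter", "chrom", "strand", "start", "end", "intensity", "n_subpeaks"],
    )
    subs = pd.DataFrame(subpeak_rows, columns=["promoter", "start", "end", "share"])

    # replicate-specific (spurious) promoters: emitted in exactly one
    # replicate of each condition, same intensity everywhere — they probe
    # replication, not condition differences
    irrep_ids = master.choice(n, size=n_irrep, replace=False) if n_irrep else np.array([], int)
    prom["reproducible"] = ~prom["promoter"].isin(irrep_ids)
    owner = master.integers(0, cfg.n_replicates, size=n)
    prom["owner_replicate"] = np.where(prom["reproducible"], -1, owner)
    prom.loc[~prom["reproducible"], "intensity"] *= cfg.irreproducible_intensity_factor

    # DE classes among reproducible promoters; shift needs >= 2 sub-peaks
    rep_ids = prom.loc[prom["reproducible"], "promoter"].to_numpy()
    n_shift = int(round(cfg.frac_shift_de * n))
    n_whole = int(round(cfg.frac_whole_de * n))
    shift_pool = prom.loc[
        prom["reproducible"] & (prom["n_subpeaks"] >= 2), "promoter"
    ].to_numpy()
    shift_ids = master.choice(shift_pool, size=min(n_shift, len(shift_pool)), replace=False)
    whole_pool = np.setdiff1d(rep_ids, shift_ids)
    whole_ids = master.choice(whole_pool, size=min(n_whole, len(whole_pool)), replace=False)
    whole_dir = master.choice([-1.0, 1.0], size=len(whole_ids))
    prom["de_class"] = "none"
    prom.loc[prom["promoter"].isin(shift_ids), "de_class"] = "shift"
    prom.loc[prom["promoter"].isin(whole_ids), "de_class"] = "whole"
    lfc = np.zeros(n)
    for wid, d in zip(whole_ids, whole_dir):
        lfc[wid] = d * np.log2(cfg.fold_change)
    prom["true_lfc"] = lfc  # promoter-level log2 FC (cond2 vs cond1); 0 for shift

    # per-condition sub-peak shares
    f = cfg.fold_change
    subs["share_cond1"] = subs["share"]
    subs["share_cond2"] = subs["share"]
    subs["true_lfc"] = 0.0
    for pid in shift_ids:
        idx = subs.index[subs["promoter"] == pid]
        a, b = idx[0], idx[1]
        t = subs.loc[[a, b], "share"].sum()
        subs.loc[a, "share_cond1"] = t * f / (1 + f)
        subs.loc[b, "share_cond1"] = t / (1 + f)
        subs.loc[a, "share_cond2"] = t / (1 + f)
        subs.loc[b, "share_cond2"] = t * f / (1 + f)
        subs.loc[a, "true_lfc"] = -np.log2(f)
        subs.loc[b, "true_lfc"] = np.log2(f)
    for ci, wid in enumerate(whole_ids):
        fac = f ** whole_dir[ci]
        idx = subs.index[subs["promoter"] == wid]
        subs.loc[idx, "share_cond2"] = subs.loc[idx, "share_cond2"] * fac
        subs.loc[idx, "true_lfc"] = np.log2(fac)

    # expand to per-site means per condition
    site_rows = []
    for prow in prom.itertuples(index=False):
        pid = prow.promoter
        for srow in subs.loc[subs["promoter"] == pid].itertuples(index=False):
            positions = np.arange(srow.start, srow.end)
            for ci, cond in enumerate(cfg.conditions):
                share = srow.share_cond1 if ci == 0 else srow.share_cond2
                mean_per_pos = prow.intensity * share / len(positions)
                for pos in positions:
                    site_rows.append((pid, cond, int(pos), prow.strand, mean_per_pos, "subpeak"))
        # broad background sites outside sub-peaks
        sub_mask = np.zeros(prow.end - prow.start, dtype=bool)
        for srow in subs.loc[subs["promoter"] == pid].itertuples(index=False):
            sub_mask[srow.start - prow.start:srow.end - prow.start] = True
        bg_positions = np.arange(prow.start, prow.end, cfg.background_step)
        bg_positions = bg_positions[~sub_mask[bg_positions - prow.start]]
        if len(bg_positions):
            for ci, cond in enumerate(cfg.conditions):
                fac = 1.0
                if prow.de_class == "whole" and ci == 1:
                    fac = f ** whole_dir[list(whole_ids).index(pid)]
                mean_per_pos = prow.intensity * cfg.background_fraction * fac / len(bg_positions)
                for pos in bg_positions:
                    site_rows.append((pid, cond, int(pos), prow.strand, mean_per_pos, "background"))
    site_means = pd.DataFrame(
        site_rows, columns=["promoter", "condition", "pos", "strand", "mean", "kind"]
    )

    gene_tss = pd.DataFrame(
        {
            "gene": [f"gene{p:04d}" for p in prom["promoter"]],
            "chrom": prom["chrom"],
            "tss": np.where(prom["strand"] == "+", prom["start"], prom["end"] - 1),
            "strand": prom["strand"],
        }
    )

    # draw counts per (condition, replicate)
    owner_of = prom.set_index("promoter")["owner_replicate"].to_dict()
    tables: dict[str, list[CTSSTable]] = {}
    sample_idx = 0
    for ci, cond in enumerate(cfg.conditions):
        tables[cond] = []
        cond_sites = site_means.loc[site_means["condition"] == cond]
        for ri in range(cfg.n_replicates):
            key = (1, ci, 0 if cfg.share_replicate_streams else ri)
            rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))
            visible = cond_sites["promoter"].map(
                lambda p: owner_of[p] == -1 or owner_of[p] == ri
            ).to_numpy()
            sites = cond_sites.loc[visible]
            counts = _nb_counts(rng, sites["mean"].to_numpy(), cfg.dispersion)
            df = pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos": sites["pos"].to_numpy(),
                    "strand": sites["strand"].to_numpy(),
                    "count": counts,
                }
            )
            # uniform background noise, independent per replicate
            n_noise = rng.poisson(cfg.noise_rate * cfg.genome_length)
            if n_noise:
                noise = pd.DataFrame(
                    {
                        "chrom": cfg.chrom,
                        "pos": rng.integers(0, cfg.genome_length, size=n_noise),
                        "strand": np.where(rng.random(n_noise) < 0.5, "+", "-"),
                        "count": 1 + rng.poisson(max(cfg.noise_mean - 1, 0), size=n_noise),
                    }
                )
                df = pd.concat([df, noise], ignore_index=True)
            df = df.loc[df["count"] > 0]
            df = df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
            tables[cond].append(CTSSTable(df[CTSS_COLUMNS]))
            sample_idx += 1

    truth = SimTruth(promoters=prom, subpeaks=subs, site_means=site_means, gene_tss=gene_tss)
    return SimResult(tables=tables, truth=truth, config=cfg)
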