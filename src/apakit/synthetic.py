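"""Synthetic APA datasets with known ground truth.

Every analysis stage needs inputs whose truth is known: usage matrices
with injected group shifts, expression rows coupled to usage at a chosen
correlation, and survival times whose hazard depends on usage. The
generator emulates the value ranges of real quantifications (usage in
[0, 1] with baselines away from the boundaries, missingness as NaN) and
writes fixtures in the same dialects the parsers consume, together with
a truth table. It does not emulate read-level noise, library-size
effects, or the correlation structure of real transcriptomes.

All randomness flows through a single integer seed; the same seed gives
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as apio
from .model import (
    APAError,
    APASite,
    ExpressionMatrix,
    GroupAssignment,
    UsageMatrix,
    UTRRegion,
)

# study-scale defaults: two groups of 30 samples, 20% of 500 features
# carrying a -0.3 usage shift over sd 0.1 measurement noise
DEFAULT_N_FEATURES = 500
DEFAULT_N_PER_GROUP = 30
DEFAULT_FRAC_AFFECTED = 0.2
DEFAULT_DELTA = -0.3
DEFAULT_NOISE_SD = 0.1


@dataclass
class SyntheticUsage:
    """A generated usage matrix with its grouping and truth table."""

    usage: UsageMatrix
    groups: GroupAssignment
    truth: pd.DataFrame  # feature_id, true_delta, affected


def gen_usage(n_features: int = DEFAULT_N_FEATURES,
              n_per_group: int = DEFAULT_N_PER_GROUP,
              frac_affected: float = DEFAULT_FRAC_AFFECTED,
              delta: float = DEFAULT_DELTA,
              noise_sd: float = DEFAULT_NOISE_SD,
              missing_rate: float = 0.0,
              kind: str = "PDUI",
              seed: int = 0) -> SyntheticUsage:
    """Generate a two-group usage matrix with injected mean shifts.

    Baseline usage per feature is uniform on (0.2, 0.8). The first
    ``frac_affected`` fraction of features shifts the second group's mean
    by ``delta``; Gaussian noise (sd ``noise_sd``) is added everywhere and
    values are clipped to [0, 1]. Clipping slightly biases means near the
    boundaries, which the bounded baseline keeps small.
    """
    if not -1 <= delta <= 1:
        raise APAError("delta must lie in [-1, 1]")
    if noise_sd <= 0:
        raise APAError("noise_sd must be > 0")
    if n_features < 1 or n_per_group < 1:
        raise APAError("n_features and n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n_affected = int(round(frac_affected * n_features))
    baseline = rng.uniform(0.2, 0.8, size=n_features)
    # keep shifted means inside [0,1] so the injected delta survives clipping
    if delta < 0:
        baseline[:n_affected] = np.maximum(baseline[:n_affected], -delta + 0.1)
    elif delta > 0:
        baseline[:n_affected] = np.minimum(baseline[:n_affected], 1 - delta - 0.1)

    n_samples = 2 * n_per_group
    means = np.tile(baseline[:, None], (1, n_samples))
    means[:n_affected, n_per_group:] += delta
    values = np.clip(means + rng.normal(0, noise_sd, size=means.shape), 0, 1)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)

    feature_ids = [f"FEAT{i:04d}" for i in range(n_features)]
    width = len(str(n_samples))
    sample_ids = ([f"g1_s{i:0{width}d}" for i in range(n_per_group)]
                  + [f"g2_s{i:0{width}d}" for i in range(n_per_group)])
    usage = UsageMatrix(kind=kind, values=pd.DataFrame(
        values, index=feature_ids, columns=sample_ids))
    mapping = {s: ("group1" if s.startswith("g1") else "group2")
               for s in sample_ids}
    groups = GroupAssignment(mapping=mapping, order=("group2", "group1"))
    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "true_delta": [delta if i < n_affected else 0.0 for i in range(n_features)],
        "true_r": 0.0,
        "true_hr": 1.0,
        "affected": [i < n_affected for i in range(n_features)],
    })
    return SyntheticUsage(usage=usage, groups=groups, truth=truth)


def gen_coupled_expression(usage_row: pd.Series, target_r: float,
                           seed: int = 0, mean_tpm: float = 100.0,
                           sd_tpm: float = 15.0) -> pd.Series:
    """An expression row correlated with a usage row at ~``target_r``.

    The latent variable is ``r * z_usage + sqrt(1 - r^2) * noise``, which
    has expected sample correlation ``target_r`` with the usage row; it
    is then mapped affinely onto a positive TPM scale (clipped at 0).
    ``|target_r| = 1`` gives the noiseless line.
    """
    if not -1 <= target_r <= 1:
        raise APAError("target_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    u = usage_row.to_numpy(dtype=float)
    ok = ~np.isnan(u)
    z = np.full(u.shape, np.nan)
    spread = np.nanstd(u)
    if spread == 0:
        raise APAError("constant usage row: cannot couple expression")
    z[ok] = (u[ok] - np.nanmean(u)) / spread
    noise = rng.normal(0, 1, size=u.shape)
    latent = target_r * z + np.sqrt(max(0.0, 1 - target_r ** 2)) * noise
    tpm = np.clip(mean_tpm + sd_tpm * latent, 0, None)
    return pd.Series(tpm, index=usage_row.index, name=usage_row.name)


def gen_coupled_survival(usage_row: pd.Series, hr: float = 1.0,
                         baseline_scale: float = 365.0,
                         censor_rate: float = 0.2,
                         seed: int = 0) -> pd.DataFrame:
    """Exponential survival whose hazard depends on standardized usage.

    The hazard of sample *i* is ``(1/baseline_scale) * hr ** z_i`` where
    ``z_i`` is the standardized usage, i.e. ``hr`` is the per-unit (one
    standard deviation of usage) hazard ratio; ``hr = 1`` is the null.
    Censoring is independent exponential, calibrated so roughly
    ``censor_rate`` of samples are censored.

    Returns a frame indexed by sample id with ``time`` and ``event``.
    """
    if hr <= 0:
        raise APAError("hazard ratio must be > 0")
    rng = np.random.default_rng(seed)
    u = usage_row.to_numpy(dtype=float)
    ok = ~np.isnan(u)
    spread = np.nanstd(u)
    z = np.zeros(u.shape)
    if spread > 0:
        z[ok] = (u[ok] - np.nanmean(u)) / spread
    hazard = (1.0 / baseline_scale) * np.power(hr, z)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # exponential censoring with P(censor) ~ censor_rate for hr = 1
        c_scale = baseline_scale * (1 - censor_rate) / censor_rate
        t_cens = rng.exponential(c_scale, size=u.shape)
    else:
        t_cens = np.full(u.shape, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time[~ok] = np.nan
    out = pd.DataFrame({"time": time, "event": event}, index=usage_row.index)
    return out


def as_dataset(synth: SyntheticUsage, source: str = "generic",
               seed: int = 0) -> apio.APADataset:
    """Embed a generated usage matrix in a genomic scaffold.

    Each feature becomes a gene on a synthetic chromosome with alternating
    strand, a proximal and a distal cleavage site, and (for the QAPA
    dialect) two transcripts whose PAU values are ``usage`` (distal) and
    ``1 - usage`` (proximal), with transcript TPMs drawn from a lognormal
    gene total.
    """
    rng = np.random.default_rng(seed + 10_000)
    sites: list[APASite] = []
    utrs: list[UTRRegion] = []
    fids = synth.usage.feature_ids
    starts = 10_000 + 50_000 * np.arange(len(fids))
    usage_df = synth.usage.values

    if source in ("dapars", "generic"):
        rows = {}
        for i, fid in enumerate(fids):
            strand = "+" if i % 2 == 0 else "-"
            chrom = f"chr{1 + i % 5}"
            a = int(starts[i])
            utr_len = int(rng.integers(500, 3000))
            prox_off = int(rng.integers(100, utr_len - 100))
            if strand == "+":
                prox, dist = a + prox_off, a + utr_len
            else:
                prox, dist = a + utr_len - prox_off, a + 1
            if source == "dapars":
                lo, hi = a + 1, a + utr_len  # full 3'UTR locus
            else:
                lo, hi = sorted((prox, dist))  # generic keeps the site span
            common = dict(gene_id=fid, gene_symbol=fid, transcript_id=fid,
                          chrom=chrom, strand=strand)
            sites.append(APASite(site_id=f"{fid}_P", cleavage_pos=prox,
                                 rank="proximal", **common))
            sites.append(APASite(site_id=f"{fid}_D", cleavage_pos=dist,
                                 rank="distal", **common))
            utrs.append(UTRRegion(transcript_id=fid, chrom=chrom, strand=strand,
                                  start=lo - 1, end=hi))
        usage = UsageMatrix(kind=synth.usage.kind, values=usage_df.copy())
        return apio.APADataset(sites=sites, utrs=utrs, usage=usage,
                               source=source)

    # qapa: two transcripts per gene sharing the 3'UTR anchor
    pau_rows = {}
    tpm_rows = {}
    order = []
    for i, fid in enumerate(fids):
        strand = "+" if i % 2 == 0 else "-"
        chrom = f"chr{1 + i % 5}"
        a = int(starts[i])
        utr_len = int(rng.integers(500, 3000))
        prox_off = int(rng.integers(100, utr_len - 100))
        if strand == "+":
            prox, dist = a + prox_off, a + utr_len
            utr_p = (a, a + prox_off)
            utr_d = (a, a + utr_len)
        else:
            end = a + utr_len
            prox, dist = end - prox_off + 1, a + 1
            utr_p = (end - prox_off, end)
            utr_d = (a, end)
        common = dict(gene_id=fid, gene_symbol=fid, chrom=chrom, strand=strand)
        sid_p, sid_d = f"{fid}_P", f"{fid}_D"
        sites.append(APASite(site_id=sid_p, transcript_id=f"{fid}.t1",
                             cleavage_pos=prox, rank="proximal", **common))
        sites.append(APASite(site_id=sid_d, transcript_id=f"{fid}.t2",
                             cleavage_pos=dist, rank="distal", **common))
        utrs.append(UTRRegion(transcript_id=f"{fid}.t1", chrom=chrom,
                              strand=strand, start=utr_p[0], end=utr_p[1]))
        utrs.append(UTRRegion(transcript_id=f"{fid}.t2", chrom=chrom,
                              strand=strand, start=utr_d[0], end=utr_d[1]))
        dist_pau = usage_df.loc[fid].to_numpy(dtype=float)
        gene_tpm = rng.lognormal(3.0, 1.0, size=dist_pau.size)
        pau_rows[sid_d] = dist_pau
        pau_rows[sid_p] = 1.0 - dist_pau
        tpm_rows[sid_d] = gene_tpm * dist_pau
        tpm_rows[sid_p] = gene_tpm * (1.0 - dist_pau)
        order += [sid_p, sid_d]

    cols = usage_df.columns
    pau = pd.DataFrame(pau_rows).T.loc[order]
    tpm = pd.DataFrame(tpm_rows).T.loc[order]
    pau.columns = cols
    tpm.columns = cols
    return apio.APADataset(
        sites=sites, utrs=utrs,
        usage=UsageMatrix(kind="PAU", values=pau),
        transcript_expression=ExpressionMatrix(values=tpm),
        source="qapa",
    )


def write_fixture(synth: SyntheticUsage, dialect: str, out_dir,
                  seed: int = 0) -> dict[str, str]:
    """Write a generated dataset as fixture files in one dialect.

    Emits ``apa_<dialect>.tsv`` plus ``truth.tsv`` under ``out_dir`` and
    returns the paths. The files parse cleanly back through the dialect
    parser.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    dataset = as_dataset(synth, source=dialect, seed=seed)
    apa_path = os.path.join(out_dir, f"apa_{dialect}.tsv")
    apio.write_apa(dataset, dialect, apa_path)
    truth_path = os.path.join(out_dir, "truth.tsv")
    synth.truth.to_csv(truth_path, sep="\t", index=False)
    return {"apa": apa_path, "truth": truth_path}


def jak1_like_dataset() -> apio.APADataset:
    """A tiny minus-strand worked-example dataset.

    Encodes a two-isoform gene modelled on JAK1: cleavage sites at
    chr1:64833213 (distal) and chr1:64834454 (proximal) with 3'UTR
    lengths 1348 and 107 bp, plus four samples of PAU/TPM values.
    """
    anchor_end = 64834454 - 1 + 107  # shared sense-strand UTR start (0-based end)
    common = dict(gene_id="GJAK1", gene_symbol="JAK1", chrom="chr1", strand="-")
    sites = [
        APASite(site_id="JAK1_1_D", transcript_id="JAK1.t1",
                cleavage_pos=64833213, rank="distal", **common),
        APASite(site_id="JAK1_2_P", transcript_id="JAK1.t2",
                cleavage_pos=64834454, rank="proximal", **common),
    ]
    utrs = [
        UTRRegion(transcript_id="JAK1.t1", chrom="chr1", strand="-",
                  start=64833212, end=anchor_end),
        UTRRegion(transcript_id="JAK1.t2", chrom="chr1", strand="-",
                  start=64834453, end=anchor_end),
    ]
    samples = ["s1", "s2", "s3", "s4"]
    pau = pd.DataFrame(
        [[0.8, 0.7, 0.3, 0.2], [0.2, 0.3, 0.7, 0.8]],
        index=["JAK1_1_D", "JAK1_2_P"], columns=samples)
    tpm = pd.DataFrame(
        [[40.0, 35.0, 15.0, 10.0], [10.0, 15.0, 35.0, 40.0]],
        index=["JAK1_1_D", "JAK1_2_P"], columns=samples)
    return apio.APADataset(
        sites=sites, utrs=utrs,
        usage=UsageMatrix(kind="PAU", values=pau),
        transcript_expression=ExpressionMatrix(values=tpm),
        source="qapa",
    )
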