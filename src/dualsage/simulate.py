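"""Synthetic dual-species SuperSAGE libraries with known ground truth.

Emulates the study design: two tag libraries of unequal depth sequenced from
plant roots — a control library containing host transcripts only and an
infected library containing a host/fungal-symbiont mixture — with a chosen
fraction of truly differentially expressed transcripts, per-base observation
errors and poly-A artifact tags.  Tag abundance follows the SAGE counting
model: one canonical tag per transcript copy, so a tag's sampling
probability is proportional to its transcript's relative abundance.

Randomness comes from two numpy Generator streams derived from the single
config seed: stream 1 drives transcriptome synthesis, stream 2 drives
library sampling, in the documented draw order (abundances, effects,
multinomial counts, errors, artifacts).  Artifacts and errors are injected
after sampling by replacing observed copies, so library totals are conserved
exactly and the truth table stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ReferenceTranscriptome
from .tags import ANCHOR, TAG_LENGTH, ConfigError, TagCountTable, extract_canonical_tag


class SimulationError(RuntimeError):
    """Inconsistent simulation state (e.g. sampling from zero abundance)."""


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ANCHOR_CODES = np.array([1, 0, 3, 2], dtype=np.intp)  # C,A,T,G in _BASES order


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Library depths default to the sequenced totals of the two root libraries
    (1,666,059 control / 3,598,159 infected tags).  Baseline transcript
    abundance is log-normal (``abundance_sigma``); true effects are
    log-uniform fold changes on ``effect_size`` applied to ``de_fraction``
    of transcripts, up or down with equal probability.  ``symbiont_load``
    is the fungal share of the infected library; the control library
    contains no symbiont material unless ``bleed_through`` is raised.
    """

    n_host_transcripts: int = 2000
    n_symbiont_transcripts: int = 500
    transcript_length: tuple[int, int] = (200, 2000)
    gc_content: float = 0.42
    de_fraction: float = 0.1
    effect_size: tuple[float, float] = (2.0, 128.0)
    depth_ctl: int = 1_666_059
    depth_inf: int = 3_598_159
    error_rate: float = 0.001
    polya_artifact_rate: float = 0.001
    symbiont_load: float = 0.10
    bleed_through: float = 0.0
    abundance_sigma: float = 1.2
    abundance_law: str = "lognormal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_host_transcripts < 0:
            raise ConfigError("n_host_transcripts must be >= 0")
        if self.n_symbiont_transcripts < 0:
            raise ConfigError("n_symbiont_transcripts must be >= 0")
        lo, hi = self.transcript_length
        if not (60 <= lo <= hi):
            raise ConfigError("transcript_length must satisfy 60 <= lo <= hi")
        if not 0 < self.gc_content < 1:
            raise ConfigError("gc_content must be in (0, 1)")
        for name in ("de_fraction", "error_rate", "polya_artifact_rate",
                     "symbiont_load", "bleed_through"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        elo, ehi = self.effect_size
        if not 1 <= elo <= ehi:
            raise ConfigError("effect_size bounds must satisfy 1 <= lo <= hi")
        if self.depth_ctl < 0 or self.depth_inf < 0:
            raise ConfigError("depth_ctl and depth_inf must be >= 0")
        if self.abundance_sigma <= 0:
            raise ConfigError("abundance_sigma must be > 0")
        if self.abundance_law != "lognormal":
            raise ConfigError("abundance_law: only 'lognormal' is implemented")


def _transcriptome_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def _library_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 2])


def _synth_transcripts(
    rng: np.random.Generator, n: int, config: SimConfig, species: str
) -> ReferenceTranscriptome:
    lo, hi = config.transcript_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lengths = rng.integers(lo, hi + 1, size=n)
    ids, seqs = [], []
    for i in range(n):
        length = int(lengths[i])
        codes = rng.choice(4, size=length, p=probs)
        # plant an anchor so the canonical-tag postcondition holds by construction:
        # an anchor at length-TAG_LENGTH has exactly TAG_LENGTH-4 downstream bases,
        # and no occurrence 3' of it can qualify.
        codes[length - TAG_LENGTH : length - TAG_LENGTH + 4] = _ANCHOR_CODES
        ids.append(f"{species}_{i:05d}")
        seqs.append(_BASES[codes].tobytes().decode("ascii"))
    return ReferenceTranscriptome(species, ids, seqs)


def simulate_transcriptomes(
    config: SimConfig,
) -> tuple[ReferenceTranscriptome, ReferenceTranscriptome]:
    """Generate host and symbiont reference transcriptomes.

    Every transcript contains at least one anchor site (CATG) with at least
    ``TAG_LENGTH - 4`` downstream bases, so a canonical tag always exists.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _transcriptome_rng(config)
    host = _synth_transcripts(rng, config.n_host_transcripts, config, "host")
    symbiont = _synth_transcripts(
        rng, config.n_symbiont_transcripts, config, "symbiont"
    )
    return host, symbiont


def _canonical_tags(ref: ReferenceTranscriptome) -> list[str]:
    tags = []
    for tid, seq in ref:
        tag = extract_canonical_tag(seq, ANCHOR, TAG_LENGTH)
        if tag is None:
            raise SimulationError(f"transcript {tid} lacks a qualifying anchor site")
        tags.append(tag)
    return tags


def _tags_to_matrix(tags: np.ndarray) -> np.ndarray:
    flat = np.frombuffer("".join(tags.tolist()).encode("ascii"), dtype=np.uint8)
    return flat.reshape(len(tags), TAG_LENGTH)


def _matrix_to_tags(mat: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(mat).view(f"S{TAG_LENGTH}")[:, 0].astype("U26")


def _apply_errors(
    rng: np.random.Generator,
    tags: np.ndarray,
    counts: np.ndarray,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate a random subset of observed copies; conserves the total count."""
    if error_rate == 0 or counts.sum() == 0:
        return tags, counts
    p_any = 1.0 - (1.0 - error_rate) ** TAG_LENGTH
    n_err = rng.binomial(counts, p_any)
    total_err = int(n_err.sum())
    counts = counts - n_err
    if total_err == 0:
        return tags, counts
    src = np.repeat(np.arange(len(tags)), n_err)
    mat = _tags_to_matrix(tags)[src]
    # number of substitutions per erroneous copy: Binomial(L, e) truncated to >= 1
    k = rng.binomial(TAG_LENGTH, error_rate, size=total_err)
    while (zero := k == 0).any():
        k[zero] = rng.binomial(TAG_LENGTH, error_rate, size=int(zero.sum()))
    order = rng.random((total_err, TAG_LENGTH)).argsort(axis=1)
    for kk in np.unique(k):
        rows = np.nonzero(k == kk)[0]
        pos = order[rows, :kk]
        old = mat[rows[:, None], pos]
        shift = rng.integers(1, 4, size=old.shape).astype(np.uint8)
        # map current base byte -> index in ACGT, add a nonzero shift mod 4
        idx = np.zeros_like(old)
        for j, b in enumerate(_BASES):
            idx[old == b] = j
        mat[rows[:, None], pos] = _BASES[(idx + shift) % 4]
    mut_tags = _matrix_to_tags(mat)
    uniq, mut_counts = np.unique(mut_tags, return_counts=True)
    all_tags = np.concatenate([tags, uniq])
    all_counts = np.concatenate([counts, mut_counts])
    return _aggregate(all_tags, all_counts)


def _apply_polya_artifacts(
    rng: np.random.Generator,
    tags: np.ndarray,
    counts: np.ndarray,
    rate: float,
    depth: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a Binomial(depth, rate) number of copies with A-rich tags."""
    if rate == 0 or depth == 0 or counts.sum() == 0:
        return tags, counts
    n_art = int(rng.binomial(depth, rate))
    n_art = min(n_art, int(counts.sum()))
    if n_art == 0:
        return tags, counts
    removed = rng.multivariate_hypergeometric(counts, n_art)
    counts = counts - removed
    mat = np.full((n_art, TAG_LENGTH), ord("A"), dtype=np.uint8)
    non_a = rng.random((n_art, TAG_LENGTH)) >= 0.9
    mat[non_a] = _BASES[rng.integers(1, 4, size=int(non_a.sum()))]
    art_tags = _matrix_to_tags(mat)
    uniq, art_counts = np.unique(art_tags, return_counts=True)
    return _aggregate(
        np.concatenate([tags, uniq]), np.concatenate([counts, art_counts])
    )


def _aggregate(tags: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(tags, return_inverse=True)
    agg = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(agg, inverse, counts)
    return uniq, agg


def simulate_tag_libraries(
    config: SimConfig,
    host: ReferenceTranscriptome,
    symbiont: ReferenceTranscriptome,
) -> tuple[TagCountTable, pd.DataFrame]:
    """Sample the two tag libraries and return observed counts plus truth.

    Counts are drawn multinomially per library from transcript relative
    abundances; the infected library mixes host and symbiont material
    (``symbiont_load``), the control library is host-only unless
    ``bleed_through`` > 0.  Per-base substitution errors and poly-A
    artifacts then replace observed copies, so column sums equal the
    configured depths exactly.

    The truth table has one row per transcript: species, canonical tag,
    within-species baseline relative abundance, true fold change (magnitude
    >= 1 plus an up/down/none direction flag, on the infected/control
    scale), and the expected tags-per-million in each library.
    """
    config.validate()
    rng = _library_rng(config)
    n_h, n_s = len(host), len(symbiont)
    if n_h + n_s == 0:
        if config.depth_ctl > 0 or config.depth_inf > 0:
            raise SimulationError("cannot sample a nonzero depth from zero abundance")
        empty = pd.DataFrame({"tag": [], "count_ctl": [], "count_inf": []})
        truth = pd.DataFrame(
            columns=["transcript_id", "species", "tag", "baseline_abundance",
                     "true_fc", "direction", "expected_cpm_ctl", "expected_cpm_inf"]
        )
        return TagCountTable(empty, 0, 0), truth

    tags_h = _canonical_tags(host)
    tags_s = _canonical_tags(symbiont)

    # draw order: baselines (host, symbiont), DE selection, magnitudes, directions
    base_h = rng.lognormal(0.0, config.abundance_sigma, n_h)
    base_s = rng.lognormal(0.0, config.abundance_sigma, n_s)
    base_h = base_h / base_h.sum() if n_h else base_h
    base_s = base_s / base_s.sum() if n_s else base_s

    n = n_h + n_s
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    lo, hi = config.effect_size
    mags = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_de))
    up = rng.random(n_de) < 0.5
    true_fc = np.ones(n)
    true_fc[de_idx] = mags
    direction = np.full(n, "none", dtype=object)
    direction[de_idx[up]] = "up"
    direction[de_idx[~up]] = "down"
    fc_mult = np.ones(n)
    fc_mult[de_idx[up]] = mags[up]
    fc_mult[de_idx[~up]] = 1.0 / mags[~up]
    # each effect is split symmetrically across the libraries (sqrt(f) up in
    # one, sqrt(f) down in the other): the between-library ratio of a DE
    # transcript is exactly f, while the per-library renormalization stays
    # near 1, so unregulated transcripts keep a stable relative abundance
    half = np.sqrt(fc_mult)

    load = config.symbiont_load if n_s else 0.0
    bleed = config.bleed_through if n_s else 0.0
    host_w_ctl = 1.0 - bleed if n_h else 0.0
    ctl_h = base_h / half[:n_h]
    ctl_s = base_s / half[n_h:]
    ctl_h = ctl_h / ctl_h.sum() * host_w_ctl if n_h else ctl_h
    ctl_s = ctl_s / ctl_s.sum() * bleed if (n_s and bleed) else np.zeros(n_s)
    p_ctl = np.concatenate([ctl_h, ctl_s])

    inf_h = base_h * half[:n_h]
    inf_s = base_s * half[n_h:]
    host_w_inf = 1.0 - load if n_h else 0.0
    inf_h = inf_h / inf_h.sum() * host_w_inf if n_h else inf_h
    inf_s = inf_s / inf_s.sum() * load if n_s else inf_s
    p_inf = np.concatenate([inf_h, inf_s])

    counts_ctl = _draw(rng, config.depth_ctl, p_ctl)
    counts_inf = _draw(rng, config.depth_inf, p_inf)

    all_tags = np.array(tags_h + tags_s)
    uniq, inv = np.unique(all_tags, return_inverse=True)
    obs_ctl = np.zeros(len(uniq), dtype=np.int64)
    obs_inf = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(obs_ctl, inv, counts_ctl)
    np.add.at(obs_inf, inv, counts_inf)

    t_ctl, c_ctl = _apply_errors(rng, uniq, obs_ctl, config.error_rate)
    t_inf, c_inf = _apply_errors(rng, uniq, obs_inf, config.error_rate)
    t_ctl, c_ctl = _apply_polya_artifacts(
        rng, t_ctl, c_ctl, config.polya_artifact_rate, config.depth_ctl
    )
    t_inf, c_inf = _apply_polya_artifacts(
        rng, t_inf, c_inf, config.polya_artifact_rate, config.depth_inf
    )

    merged = pd.merge(
        pd.DataFrame({"tag": t_ctl, "count_ctl": c_ctl}),
        pd.DataFrame({"tag": t_inf, "count_inf": c_inf}),
        on="tag",
        how="outer",
    ).fillna(0)
    merged = merged[(merged["count_ctl"] + merged["count_inf"]) > 0]
    merged = merged.sort_values("tag", kind="stable").reset_index(drop=True)
    merged["count_ctl"] = merged["count_ctl"].astype(int)
    merged["count_inf"] = merged["count_inf"].astype(int)
    table = TagCountTable(merged, config.depth_ctl, config.depth_inf)

    truth = pd.DataFrame(
        {
            "transcript_id": host.ids + symbiont.ids,
            "species": ["host"] * n_h + ["symbiont"] * n_s,
            "tag": all_tags,
            "baseline_abundance": np.concatenate([base_h, base_s]),
            "true_fc": true_fc,
            "direction": direction,
            "expected_cpm_ctl": p_ctl * 1e6,
            "expected_cpm_inf": p_inf * 1e6,
        }
    )
    return table, truth


def _draw(rng: np.random.Generator, depth: int, p: np.ndarray) -> np.ndarray:
    if depth == 0:
        return np.zeros(len(p), dtype=np.int64)
    total = p.sum()
    if total <= 0:
        raise SimulationError("cannot sample a nonzero depth from zero abundance")
    return rng.multinomial(depth, p / total)
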