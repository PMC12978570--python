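"""Canonical desk-scale synthetic studies.

Two end-to-end study designs exercise the full pipeline on the bundled
soundscape simulator:

* **Separability** — one site emitting three spectrally well-separated
  archetypes at +20 dB band-limited SNR.  After tiny-preset contrastive
  training, k-means (k=3) on the embeddings is scored by ARI against
  the generator's segment labels.
* **Dictionary recovery** — two sites sharing archetype A, with
  archetype B exclusive to site 1 and C exclusive to site 2.  After
  training, joint GMM clustering, cohesion filtering, and the
  site-presence rule, the dictionary should report A at both sites and
  B/C only at their home sites.

The study sizes (clips per site, steps, joint-cluster k) are the
package's scaled-down defaults; archetype bands and SNR are the study
conditions themselves.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .clustering import ari, cluster_embeddings
from .discovery import (
    build_dictionary,
    describe_signature,
    filter_clusters,
    joint_cluster,
)
from .models import ModelConfig
from .preprocess import SpectrogramConfig
from .synth import NOISE_LABEL, ArchetypeSpec, SiteRecipe, build_dataset
from .training import (
    GLOBAL_FRAMES,
    SegmentDataset,
    TrainingConfig,
    embed,
    embedding_matrix,
    resize_view,
    train,
)
from .views import energy_center

__all__ = [
    "three_archetype_recipe",
    "two_site_recipes",
    "separability_study",
    "dictionary_recovery_study",
]


def _tonal(name: str = "tonal") -> ArchetypeSpec:
    return ArchetypeSpec(
        name=name, kind="harmonic_tonal", band=(60.0, 480.0),
        duration_range=(1.2, 1.8), f0_range=(95.0, 105.0),
        n_harmonics=4, jitter=0.05,
    )


def _pulse(name: str = "pulse") -> ArchetypeSpec:
    return ArchetypeSpec(
        name=name, kind="pulse_train", band=(500.0, 800.0),
        duration_range=(1.2, 1.8), pulse_rate_range=(18.0, 22.0), jitter=0.05,
    )


def _vessel(name: str = "vessel") -> ArchetypeSpec:
    return ArchetypeSpec(
        name=name, kind="vessel_narrowband", band=(40.0, 120.0),
        duration_range=(1.5, 2.0), f0_range=(60.0, 90.0), jitter=0.05,
    )


def three_archetype_recipe(snr_db: float = 20.0) -> SiteRecipe:
    """One site, three well-separated archetypes at fixed band-limited SNR."""
    arch = (_tonal(), _pulse(), _vessel())
    return SiteRecipe(
        site_id="S1",
        archetypes=arch,
        archetype_weights={a.name: 1.0 for a in arch},
        snr_db_range=(snr_db, snr_db),
        events_per_clip_range=(4, 7),
        overlap_prob=0.0,
    )


def two_site_recipes(snr_db: float = 20.0) -> Tuple[SiteRecipe, SiteRecipe]:
    """Shared archetype A; B exclusive to site 1, C exclusive to site 2."""
    a, b, c = _tonal("arch_A"), _pulse("arch_B"), _vessel("arch_C")
    site1 = SiteRecipe(
        site_id="site1", archetypes=(a, b),
        archetype_weights={"arch_A": 1.0, "arch_B": 1.0},
        snr_db_range=(snr_db, snr_db), events_per_clip_range=(4, 7),
    )
    site2 = SiteRecipe(
        site_id="site2", archetypes=(a, c),
        archetype_weights={"arch_A": 1.0, "arch_C": 1.0},
        snr_db_range=(snr_db, snr_db), events_per_clip_range=(4, 7),
    )
    return site1, site2


def _tiny_training_config(steps: int) -> TrainingConfig:
    return TrainingConfig(steps=steps, batch_size=32, bank_capacity=512)


def separability_study(seed: int, n_clips: int = 24, steps: int = 300,
                       out_dir=None) -> Dict[str, float]:
    """Train the tiny preset on 3-archetype data; score k-means recovery."""
    with tempfile.TemporaryDirectory() as tmp:
        target = Path(out_dir) if out_dir else Path(tmp)
        manifest = build_dataset([three_archetype_recipe()], n_clips, target, rng_seed=seed)
        dataset = SegmentDataset(manifest)
        state = train(dataset, ModelConfig(), _tiny_training_config(steps), seed=seed)
        table = embed(dataset, state)
        labeled = table[table["dominant_archetype"] != NOISE_LABEL]
        x = embedding_matrix(labeled)
        assignment = cluster_embeddings(x, "kmeans", k=3, seed=seed)
        score = ari(labeled["dominant_archetype"].to_numpy(), assignment.labels)
        result = dict(
            ari=float(score),
            n_segments=len(labeled),
            loss_first=state.history[0]["l_ctr"],
            loss_last=state.history[-1]["l_ctr"],
            embedding_min_dim_std=float(embedding_matrix(table).std(axis=0).min()),
        )
    return result


def _deterministic_crop(dataset: SegmentDataset, idx: int) -> np.ndarray:
    ctx = dataset.context(idx)
    center = energy_center(ctx)
    start = int(np.clip(center - GLOBAL_FRAMES // 2, 0,
                        max(ctx.shape[0] - GLOBAL_FRAMES, 0)))
    return ctx[start : start + GLOBAL_FRAMES]


def dictionary_recovery_study(
    seed: int,
    n_clips_per_site: int = 20,
    steps: int = 250,
    k: int = 8,
    cohesion_threshold: float = 0.10,
    presence_min_count: int = 10,
) -> Dict[str, object]:
    """Two-site discovery: shared archetype at both sites, exclusives at home."""
    with tempfile.TemporaryDirectory() as tmp:
        recipes = two_site_recipes()
        manifest = build_dataset(recipes, n_clips_per_site, Path(tmp), rng_seed=seed)
        dataset = SegmentDataset(manifest)
        state = train(dataset, ModelConfig(), _tiny_training_config(steps), seed=seed)
        table = embed(dataset, state)
        x = embedding_matrix(table)
        assignment = joint_cluster(x, k=k, seed=seed)
        retained, coh = filter_clusters(assignment, x, threshold=cohesion_threshold)

        signatures = []
        for cid in retained:
            mask = assignment.labels == cid
            idxs = np.flatnonzero(mask)
            specs = [_deterministic_crop(dataset, int(i)) for i in idxs]
            signatures.append(
                describe_signature(
                    cid, specs, x[mask],
                    table["site_id"].to_numpy()[mask],
                    member_keys=idxs.tolist(),
                )
            )
        dictionary = build_dictionary(signatures, presence_min_count=presence_min_count)

        labels = table["dominant_archetype"].to_numpy()
        result: Dict[str, object] = dict(
            n_retained=len(retained),
            n_multi_site=dictionary.n_multi_site,
            n_single_site=dictionary.n_single_site,
        )
        home = {"arch_A": {"site1", "site2"}, "arch_B": {"site1"}, "arch_C": {"site2"}}
        for arch, expected_sites in home.items():
            cid = _plurality_cluster(labels, assignment.labels, retained, arch)
            if cid is None:
                result[f"{arch}_recovered"] = False
                result[f"{arch}_cohesion"] = float("nan")
                continue
            sites = set(dictionary.sites_of(cid))
            result[f"{arch}_recovered"] = sites == expected_sites
            result[f"{arch}_cohesion"] = coh[cid]
        result["recovered_all"] = all(
            result[f"{a}_recovered"] for a in ("arch_A", "arch_B", "arch_C")
        )
    return result


def _plurality_cluster(labels: np.ndarray, assignment: np.ndarray,
                       retained: List[int], archetype: str) -> Optional[int]:
    """Retained cluster holding the most segments of the given archetype."""
    mask = labels == archetype
    if not mask.any():
        return None
    counts = pd.Series(assignment[mask]).value_counts()
    for cid in counts.index:
        if cid in retained:
            return int(cid)
    return None
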