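"""Distribution-learning metrics for generated molecule sets.

The suite scores a sample of generated SMILES against reference corpora:

- ``validity``: % of strings that parse back into molecular graphs;
- ``uniqueness``: % of distinct canonical structures among valid ones;
- ``novelty``: % of distinct structures absent from the training set;
- ``active_rate``: mean of the active fractions among novel structures and
  among all valid generated molecules (active = screening probability
  strictly above 0.5);
- ``internal_diversity``: mean pairwise Tanimoto *distance* (1 - sim);
- ``snn``: mean similarity of each generated molecule to its nearest
  reference neighbor;
- ``frag_similarity`` / ``scaff_similarity``: cosine similarity between
  BRICS-fragment or Bemis-Murcko-scaffold frequency vectors;
- ``frechet_distance``: Frechet distance between Gaussians fit to feature
  clouds under a pluggable featurizer (default: the standardized
  physico-chemical descriptor panel — deliberately *not* numerically
  comparable to published neural-feature Frechet scores).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import linalg

from .chem import Corpus, canonicalize
from .descriptors import DescriptorFeaturizer, EcfpFeaturizer, bulk_tanimoto


@dataclass
class GenerationReport:
    """Metric vector for one generated sample against its references."""

    valid: float
    unique: float
    novel: float
    active: float | None
    diversity: float
    snn: float
    frag: float
    scaff: float
    frechet: float
    n_generated: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        txt = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt


# ---------------------------------------------------------------------------
# helpers

def _valid_canonical(generated: list[str]) -> list[str]:
    out = []
    for s in generated:
        c = canonicalize(s)
        if c is not None and c != "":
            out.append(c)
    return out


def _canon_set(corpus) -> set[str]:
    if isinstance(corpus, Corpus):
        return set(corpus.smiles())
    return {c for c in (canonicalize(s) for s in corpus) if c}


def _fingerprints(smiles: list[str]) -> np.ndarray:
    return EcfpFeaturizer().fit_transform(smiles)


# ---------------------------------------------------------------------------
# counting metrics (percentages)

def validity(generated: list[str]) -> float:
    """Percentage of strings that parse and sanitize to molecular graphs."""
    if not generated:
        raise ValueError("empty generated list")
    return 100.0 * len(_valid_canonical(generated)) / len(generated)


def uniqueness(generated: list[str]) -> float:
    """Percentage of distinct canonical SMILES among the valid ones."""
    valid = _valid_canonical(generated)
    if not valid:
        raise ValueError("no valid molecules")
    return 100.0 * len(set(valid)) / len(valid)


def novelty(generated: list[str], training) -> float:
    """Percentage of distinct valid structures not present in training."""
    valid = _valid_canonical(generated)
    if not valid:
        raise ValueError("no valid molecules")
    distinct = set(valid)
    train = _canon_set(training)
    return 100.0 * len(distinct - train) / len(distinct)


def active_rate(generated: list[str], classifier, training) -> float:
    """Mean of the active fractions among novel structures and all valid ones.

    ``classifier`` is a fitted :class:`~gelgen.screening.GelationClassifier`.
    """
    valid = _valid_canonical(generated)
    if not valid:
        raise ValueError("no valid molecules")
    train = _canon_set(training)
    novel = sorted(set(valid) - train)
    res_all = classifier.screen(valid)
    frac_all = float(np.mean(res_all.active))
    if novel:
        res_novel = classifier.screen(novel)
        frac_novel = float(np.mean(res_novel.active))
    else:
        frac_novel = 0.0
    return 100.0 * 0.5 * (frac_novel + frac_all)


# ---------------------------------------------------------------------------
# similarity metrics

def internal_diversity(smiles: list[str]) -> float:
    """Mean pairwise Tanimoto distance (1 - similarity) over unordered pairs."""
    valid = _valid_canonical(smiles)
    if len(valid) < 2:
        raise ValueError("diversity needs at least 2 valid molecules")
    F = _fingerprints(valid)
    sim = bulk_tanimoto(F, F)
    iu = np.triu_indices(len(valid), k=1)
    return float(np.mean(1.0 - sim[iu]))


def snn(generated: list[str], reference) -> float:
    """Mean max-similarity of each generated molecule to the reference set."""
    gen = _valid_canonical(generated)
    ref = sorted(_canon_set(reference))
    if not gen or not ref:
        raise ValueError("both sets must contain valid molecules")
    sim = bulk_tanimoto(_fingerprints(gen), _fingerprints(ref))
    return float(np.mean(sim.max(axis=1)))


def _brics_fragments(smiles: list[str]) -> Counter:
    counts: Counter = Counter()
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        frags = BRICS.BRICSDecompose(mol)
        counts.update(frags)
    return counts


def _murcko_scaffolds(smiles: list[str]) -> Counter:
    counts: Counter = Counter()
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        scaff = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
        if scaff:
            counts.update([scaff])
    return counts


def _cosine_counts(a: Counter, b: Counter) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    keys = sorted(set(a) | set(b))
    va = np.array([a.get(k, 0) for k in keys], dtype=float)
    vb = np.array([b.get(k, 0) for k in keys], dtype=float)
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


def frag_similarity(generated: list[str], reference) -> float:
    """Cosine similarity of BRICS-fragment frequency vectors of the two sets."""
    gen = _valid_canonical(generated)
    ref = sorted(_canon_set(reference))
    if not gen or not ref:
        raise ValueError("both sets must contain valid molecules")
    return _cosine_counts(_brics_fragments(gen), _brics_fragments(ref))


def scaff_similarity(generated: list[str], reference) -> float:
    """Cosine similarity of Bemis-Murcko scaffold frequency vectors."""
    gen = _valid_canonical(generated)
    ref = sorted(_canon_set(reference))
    if not gen or not ref:
        raise ValueError("both sets must contain valid molecules")
    return _cosine_counts(_murcko_scaffolds(gen), _murcko_scaffolds(ref))


# ---------------------------------------------------------------------------
# Frechet distance

def _default_featurizer(smiles: list[str]) -> np.ndarray:
    return DescriptorFeaturizer().fit_transform(smiles)


def frechet_distance(
    generated: list[str],
    reference,
    featurizer=None,
    eps: float = 1e-6,
) -> float:
    """Frechet distance between Gaussian fits of the two feature clouds.

    ``|mu1 - mu2|^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``.  ``featurizer`` maps a
    list of SMILES to an (n, d) array; the default is the standardized
    descriptor panel.  Degenerate covariances get a small diagonal ridge.
    """
    gen = _valid_canonical(generated)
    ref = sorted(_canon_set(reference))
    if len(gen) < 2 or len(ref) < 2:
        raise ValueError("both sets need at least 2 valid molecules")
    featurizer = featurizer or _default_featurizer
    A, B = np.asarray(featurizer(gen), float), np.asarray(featurizer(ref), float)
    # standardize jointly so heterogeneous descriptor scales do not dominate
    both = np.vstack([A, B])
    mu, sd = both.mean(0), both.std(0)
    sd[sd == 0] = 1.0
    A, B = (A - mu) / sd, (B - mu) / sd
    return gaussian_frechet(A.mean(0), np.cov(A.T), B.mean(0), np.cov(B.T), eps=eps)


def gaussian_frechet(mu1, sigma1, mu2, sigma2, eps: float = 1e-6) -> float:
    """Closed-form Frechet distance between two Gaussians."""
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    sigma1, sigma2 = np.atleast_2d(sigma1), np.atleast_2d(sigma2)
    diff = mu1 - mu2
    covmean = np.asarray(linalg.sqrtm(sigma1 @ sigma2))
    if not np.isfinite(covmean).all():
        ridge = eps * np.eye(sigma1.shape[0])
        covmean = np.asarray(linalg.sqrtm((sigma1 + ridge) @ (sigma2 + ridge)))
    covmean = np.real(covmean)
    val = diff @ diff + np.trace(sigma1 + sigma2 - 2.0 * covmean)
    return float(max(val, 0.0))


# ---------------------------------------------------------------------------
# report

def evaluate(
    generated: list[str],
    training,
    reference,
    classifier=None,
    featurizer=None,
) -> GenerationReport:
    """Full metric report for a generated sample.

    ``training`` is the corpus used for novelty; ``reference`` the held-out
    set for SNN/Frag/Scaff/Frechet.  ``classifier`` (optional) enables the
    active-rate metric.
    """
    return GenerationReport(
        valid=validity(generated),
        unique=uniqueness(generated),
        novel=novelty(generated, training),
        active=None if classifier is None else active_rate(generated, classifier, training),
        diversity=internal_diversity(generated),
        snn=snn(generated, reference),
        frag=frag_similarity(generated, reference),
        scaff=scaff_similarity(generated, reference),
        frechet=frechet_distance(generated, reference, featurizer=featurizer),
        n_generated=len(generated),
        metadata={
            "novelty_denominator": "distinct valid molecules",
            "fragment_rule": "BRICS decomposition",
            "scaffold_rule": "Bemis-Murcko framework",
            "frechet_featurizer": "standardized descriptor panel"
            if featurizer is None
            else "custom",
        },
    )
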