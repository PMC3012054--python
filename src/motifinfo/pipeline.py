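"""End-to-end orchestration: configuration, logging, and the discover /
characterize runs that produce the output tables (motif list, enrichment
heatmap, instance list, PWMs, interaction map, position histograms)."""

from __future__ import annotations

import logging
import os
import shutil
from dataclasses import dataclass, field

import numpy as np

from . import characterize, io, stats
from .discovery import DiscoveryConfig, discover
from .motif import build_profile, parse_motif, pwm_from_instances

logger = logging.getLogger("motifinfo")


@dataclass
class RunConfig:
    """Validated inputs and options for a pipeline run."""

    fasta: str
    behavior: str
    out_dir: str
    seed: int = 0
    quantitative: bool = False
    n_bins: int = 10
    domains: str | None = None
    terms: str | None = None
    disorder: str | None = None
    known_motifs: str | None = None
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    characterization_n_rand: int = 10000

    def validate(self) -> None:
        for label, path in [
            ("fasta", self.fasta),
            ("behavior", self.behavior),
            ("domains", self.domains),
            ("terms", self.terms),
            ("disorder", self.disorder),
            ("known_motifs", self.known_motifs),
        ]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label} file not found: {path}")


def _setup_run_log(out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _load_inputs(config: RunConfig):
    proteome = io.read_fasta(config.fasta)
    behavior = io.read_behavior(
        config.behavior,
        "quantitative" if config.quantitative else "discrete",
        proteome,
        n_bins=config.n_bins,
    )
    logger.info(
        "loaded %d proteins, %d in behavior universe, %d classes",
        len(proteome),
        len(behavior.ids),
        behavior.n_classes,
    )
    return proteome, behavior


def _characterize_results(results, proteome, behavior, config: RunConfig) -> None:
    """Write interaction map, enrichment table, and position histograms."""
    out_dir = config.out_dir
    n_rand = config.characterization_n_rand
    domains = io.read_intervals(config.domains, proteome, "domain") if config.domains else None
    terms = io.read_terms(config.terms, proteome) if config.terms else None
    disorder = io.read_intervals(config.disorder, proteome, "disorder") if config.disorder else None
    catalog = io.read_known_motifs(config.known_motifs) if config.known_motifs else None
    universe = set(behavior.ids)

    biases = {}
    for r in results:
        b = characterize.positional_bias(
            r.profile,
            behavior,
            proteome,
            n_rand=n_rand,
            seed=stats.derive_seed(config.seed, "posbias", str(r.motif)),
        )
        biases[str(r.motif)] = b
        path = os.path.join(out_dir, f"positions_{r.motif}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# normalized position histograms, 10 bins over [0,1]\n")
            fh.write("bin\ttargets\tothers\n")
            for i in range(len(b.histogram_targets)):
                fh.write(f"{i}\t{int(b.histogram_targets[i])}\t{int(b.histogram_others[i])}\n")

    with open(os.path.join(out_dir, "interactions.tsv"), "w", encoding="utf-8") as fh:
        fh.write(f"# n_rand={n_rand}\n")
        fh.write(
            "motif_a\tmotif_b\tcooccurrence_mi_bits\tcooccurrence_p\tdirection"
            "\tcolocalized\tcolocalization_p\n"
        )
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                inter = characterize.interaction(
                    results[i].profile,
                    results[j].profile,
                    behavior,
                    n_rand=n_rand,
                    seed=stats.derive_seed(config.seed, "interaction", i, j),
                )
                fh.write(
                    "\t".join(
                        [
                            str(inter.motif_a),
                            str(inter.motif_b),
                            f"{inter.cooccurrence_mi:.6g}",
                            f"{inter.cooccurrence_p:.6g}",
                            inter.direction,
                            "+" if inter.colocalized else "-",
                            "NA" if inter.colocalization_p is None else f"{inter.colocalization_p:.6g}",
                        ]
                    )
                    + "\n"
                )

    with open(os.path.join(out_dir, "enrichment_table.tsv"), "w", encoding="utf-8") as fh:
        fh.write(f"# n_rand={n_rand}\n")
        fh.write(
            "motif\tposition_bias\tposition_bias_p\tbest_term\tbest_term_p"
            "\tbest_domain\tbest_domain_p\tdomain_overlap_z\tdisorder_score\tbest_known_match\n"
        )
        for r in results:
            b = biases[str(r.motif)]
            pos_flag = "-"
            pos_p = "NA"
            if not b.insufficient:
                pos_p = f"{b.empirical_p:.6g}"
                pos_flag = "Y" if b.empirical_p < 0.01 else "-"
            best_term = best_term_p = "NA"
            if terms is not None:
                ranked = characterize.term_enrichment(
                    r.profile.carrier_ids(), terms, universe
                )
                if ranked:
                    best_term, p, _ = ranked[0]
                    best_term_p = f"{p:.3g}"
            best_dom = best_dom_p = dom_z = "NA"
            if domains is not None:
                reports = characterize.domain_report(r.profile, domains, proteome)
                if reports:
                    top = reports[0]
                    best_dom = top.domain_name
                    best_dom_p = f"{top.cooccurrence_p:.3g}"
                    dom_z = "NA" if top.overlap_z is None else f"{top.overlap_z:.2f}"
            dis = "NA"
            if disorder is not None and r.profile.n_instances():
                dis = f"{characterize.disorder_score(r.profile, disorder, proteome):.3f}"
            known = "NA"
            if catalog is not None:
                m = characterize.best_match(r.motif, catalog)
                if m is not None:
                    known = f"{m[1]} ({m[0]}, {m[2]:.2f})"
            fh.write(
                "\t".join(
                    [str(r.motif), pos_flag, pos_p, best_term, best_term_p, best_dom, best_dom_p, dom_z, dis, known]
                )
                + "\n"
            )


def run_discover(config: RunConfig) -> list:
    """Full pipeline: read inputs, discover motifs, characterize, write tables.

    Removes partial outputs and re-raises on any hard error. Returns the
    discovered :class:`~motifinfo.discovery.MotifResult` list.
    """
    config.validate()
    handler = _setup_run_log(config.out_dir)
    try:
        logger.info("run_discover: seed=%d config=%s", config.seed, config.discovery)
        proteome, behavior = _load_inputs(config)
        config.discovery.seed = config.seed
        results = discover(proteome, behavior, config.discovery)
        io.write_results(results, config.out_dir, class_labels=behavior.class_labels)
        _characterize_results(results, proteome, behavior, config)
        config.discovery.to_file(os.path.join(config.out_dir, "config.txt"))
        logger.info("run_discover: wrote %d motifs to %s", len(results), config.out_dir)
        return results
    except Exception:
        logger.exception("run_discover failed; removing partial outputs")
        for name in os.listdir(config.out_dir):
            if name != "run.log":
                path = os.path.join(config.out_dir, name)
                shutil.rmtree(path) if os.path.isdir(path) else os.remove(path)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_characterize(config: RunConfig, motif_patterns: list[str]) -> list:
    """Characterization suite on user-supplied motifs, skipping discovery.

    Each pattern is parsed, profiled across the proteome, tested for
    significance and robustness, and written through the same output tables
    as :func:`run_discover`. Unparseable motifs raise with the offending
    pattern named.
    """
    from .discovery import MotifResult

    config.validate()
    handler = _setup_run_log(config.out_dir)
    try:
        proteome, behavior = _load_inputs(config)
        results = []
        for pattern in motif_patterns:
            try:
                motif = parse_motif(pattern)
            except Exception as e:
                raise ValueError(f"cannot parse motif {pattern!r}: {e}") from e
            profile = build_profile(proteome, motif, behavior.ids)
            test = stats.shuffle_test(
                profile.present,
                behavior.classes,
                n_rand=config.characterization_n_rand,
                seed=stats.derive_seed(config.seed, "characterize-test", pattern),
            )
            rob = stats.robustness(
                motif,
                proteome,
                behavior,
                seed=stats.derive_seed(config.seed, "characterize-robustness", pattern),
            )
            results.append(
                MotifResult(
                    motif=motif,
                    mi=test.observed_mi,
                    test=test,
                    robustness=rob,
                    enrichment=stats.class_enrichment(profile, behavior),
                    profile=profile,
                    seed_kmer="",
                    pwm=pwm_from_instances(profile, proteome) if profile.n_instances() else None,
                )
            )
        io.write_results(results, config.out_dir, class_labels=behavior.class_labels)
        _characterize_results(results, proteome, behavior, config)
        return results
    except Exception:
        logger.exception("run_characterize failed; removing partial outputs")
        for name in os.listdir(config.out_dir):
            if name != "run.log":
                path = os.path.join(config.out_dir, name)
                shutil.rmtree(path) if os.path.isdir(path) else os.remove(path)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
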