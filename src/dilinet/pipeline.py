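"""End-to-end study replica: simulate/load -> clean -> signals -> describe
-> network -> enrich, under one JSON config with a machine-readable manifest.

The run config is a single JSON document; all paths are resolved relative
to the config file's directory. Stage outputs are written to ``out_dir``
and their SHA-256 checksums recorded in ``manifest.json``, so two runs of
the same config and seed can be compared checksum-by-checksum (the
manifest also carries wall-clock timings, which naturally differ).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import __version__
from ._common import ConfigError, StageError, logger
from . import descriptive, disproportionality, enrichment, network, reports
from .meddra import load_dictionary, expand_query
from .synthetic import SimulationConfig, simulate_database, write_reports_csv


@dataclass
class RunConfig:
    """Validated inputs and thresholds of one pipeline run."""

    out_dir: Path
    dictionary: Path
    drugs: list[str]
    reports: Path | None = None
    simulate: SimulationConfig | None = None
    synonyms: Path | None = None
    smq_codes: list[str] | None = None
    scope: str = "combined"
    min_count: int = 3
    targets: Path | None = None
    disease_genes: Path | None = None
    edges: Path | None = None
    gmt: Path | None = None
    min_score: float = 0.7
    top_k: int = 10
    top_pathways: int = 20
    seed: int | None = None

    def validate(self) -> None:
        if self.reports is None and self.simulate is None:
            raise ConfigError("reports: either a reports path or a simulate block is required")
        if not self.drugs:
            raise ConfigError("drugs: at least one study drug is required")
        if self.scope not in ("narrow", "combined"):
            raise ConfigError(f"scope: must be narrow|combined, got {self.scope!r}")
        if self.min_count < 1:
            raise ConfigError(f"min_count: must be >= 1, got {self.min_count}")
        if not 0.0 <= self.min_score <= 1.0:
            raise ConfigError(f"min_score: must be in [0,1], got {self.min_score}")
        if self.top_k < 1:
            raise ConfigError(f"top_k: must be >= 1, got {self.top_k}")
        if self.top_pathways < 1:
            raise ConfigError(f"top_pathways: must be >= 1, got {self.top_pathways}")
        network_paths = (self.targets, self.disease_genes, self.edges)
        if any(p is not None for p in network_paths) and not all(
            p is not None for p in network_paths
        ):
            raise ConfigError("targets/disease_genes/edges: all three or none must be set")
        for name in ("dictionary", "reports", "synonyms", "targets", "disease_genes", "edges", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: path does not exist: {p}")

    @classmethod
    def from_json(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        base = Path(path).parent
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data.update(overrides or {})

        def resolve(key):
            return (base / data[key]).resolve() if data.get(key) else None

        sim = None
        if data.get("simulate"):
            sim = SimulationConfig.from_json_dict(data["simulate"])
        try:
            cfg = cls(
                out_dir=Path(data["out_dir"]) if Path(data["out_dir"]).is_absolute()
                else (base / data["out_dir"]).resolve(),
                dictionary=resolve("dictionary"),
                drugs=list(data["drugs"]),
                reports=resolve("reports"),
                simulate=sim,
                synonyms=resolve("synonyms"),
                smq_codes=data.get("smq_codes"),
                scope=data.get("scope", "combined"),
                min_count=int(data.get("min_count", 3)),
                targets=resolve("targets"),
                disease_genes=resolve("disease_genes"),
                edges=resolve("edges"),
                gmt=resolve("gmt"),
                min_score=float(data.get("min_score", 0.7)),
                top_k=int(data.get("top_k", 10)),
                top_pathways=int(data.get("top_pathways", 20)),
                seed=data.get("seed"),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config field: {exc.args[0]}") from None
        if cfg.dictionary is None:
            raise ConfigError("dictionary: required")
        return cfg


@dataclass
class RunManifest:
    """What a run produced: config echo, per-stage counts and timings, and
    SHA-256 checksums of every declared output file."""

    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in order; any stage failure raises
    :class:`StageError` naming the stage, preserving prior outputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=_config_echo(cfg))

    def record(name: str, t0: float, **counts) -> None:
        manifest.stages.append(
            {"name": name, "seconds": round(time.monotonic() - t0, 3), **counts}
        )

    def declare(path: Path) -> Path:
        manifest.outputs[path.name] = ""
        return path

    try:
        # -- simulate (optional) ------------------------------------------
        reports_path = cfg.reports
        if cfg.simulate is not None:
            t0 = time.monotonic()
            sim = cfg.simulate
            if cfg.seed is not None:
                sim = SimulationConfig.from_json_dict({**sim.to_json_dict(), "seed": cfg.seed})
            frame, truth = simulate_database(sim)
            reports_path = declare(out / "reports.csv")
            write_reports_csv(frame, reports_path)
            truth.write_json(declare(out / "truth.json"))
            record("simulate", t0, rows=len(frame), cases=sim.n_cases)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        t0 = time.monotonic()
        synonyms = reports.read_synonyms(cfg.synonyms) if cfg.synonyms else None
        records, issues = reports.read_reports_detailed(reports_path)
        clean = reports.deduplicate(records, synonyms)
        record(
            "clean",
            t0,
            rows_rejected=len(issues),
            **clean.counters,
            n_reports=clean.n_reports,
            multi_drug_cases=len(reports.multi_drug_cases(clean, cfg.drugs, synonyms)),
        )
    except Exception as exc:
        raise StageError("clean", exc) from exc

    try:
        t0 = time.monotonic()
        d = load_dictionary(cfg.dictionary)
        smq_codes = cfg.smq_codes if cfg.smq_codes else d.codes_at_level("smq")
        pt_codes = sorted(
            set().union(*(expand_query(d, "smq", c, cfg.scope) for c in smq_codes))
        )
        hlt_codes = sorted({d.pts[c].hlt_code for c in pt_codes})
        for level, codes, fname in (
            ("smq", smq_codes, "signals_smq.csv"),
            ("hlt", hlt_codes, "signals_hlt.csv"),
            ("pt", pt_codes, "signals_pt.csv"),
        ):
            results = disproportionality.scan_signals(
                clean, cfg.drugs, d, level, codes, cfg.scope, cfg.min_count, synonyms
            )
            disproportionality.results_to_frame(results).to_csv(
                declare(out / fname), index=False, lineterminator="\n"
            )
        record("signals", t0, smq=len(smq_codes), hlt=len(hlt_codes), pt=len(pt_codes))
    except Exception as exc:
        raise StageError("signals", exc) from exc

    try:
        t0 = time.monotonic()
        dili_pts = frozenset(pt_codes)
        summaries = {
            drug: descriptive.summarize_cohort(clean, drug, dili_pts, synonyms).to_dict()
            for drug in cfg.drugs
        }
        with open(declare(out / "descriptive.json"), "w", encoding="utf-8") as fh:
            json.dump(summaries, fh, indent=1, sort_keys=True)
            fh.write("\n")
        record("describe", t0, drugs=len(cfg.drugs))
    except Exception as exc:
        raise StageError("describe", exc) from exc

    intersection = None
    if cfg.targets is not None:
        try:
            t0 = time.monotonic()
            targets = network.read_gene_list(cfg.targets, "drug_targets")
            disease = network.read_gene_list(cfg.disease_genes, "disease_genes")
            intersection = network.intersect_gene_sets(targets, disease)
            (declare(out / "intersection.txt")).write_text(
                "\n".join(sorted(intersection.symbols)) + "\n", encoding="utf-8"
            )
            edges = network.read_edge_list(cfg.edges)
            net = network.build_network(intersection, edges, cfg.min_score)
            nodes_df, edges_df = network.network_frames(net)
            nodes_df.to_csv(declare(out / "nodes.csv"), index=False, lineterminator="\n")
            edges_df.to_csv(declare(out / "edges.csv"), index=False, lineterminator="\n")
            hubs = network.rank_hubs(net, min(cfg.top_k, max(net.number_of_nodes(), 1)))
            with open(declare(out / "hubs.csv"), "w", encoding="utf-8", newline="\n") as fh:
                fh.write("gene,degree\n")
                for g, deg in hubs:
                    fh.write(f"{g},{deg}\n")
            nx.write_gml(net, declare(out / "network.gml"))
            record(
                "network",
                t0,
                targets=len(targets),
                disease=len(disease),
                intersection=len(intersection),
                nodes=net.number_of_nodes(),
                edges=net.number_of_edges(),
            )
        except Exception as exc:
            raise StageError("network", exc) from exc

    if cfg.gmt is not None and intersection is not None:
        try:
            t0 = time.monotonic()
            coll = enrichment.read_gmt(cfg.gmt)
            results = enrichment.enrich(intersection, coll, top=cfg.top_pathways)
            enrichment.results_to_frame(results).to_csv(
                declare(out / "enrichment.csv"), index=False, lineterminator="\n"
            )
            enrichment.bubble_frame(results).to_csv(
                declare(out / "bubble.csv"), index=False, lineterminator="\n"
            )
            record("enrich", t0, pathways=len(coll.pathways), reported=len(results))
        except Exception as exc:
            raise StageError("enrich", exc) from exc

    for name in manifest.outputs:
        manifest.outputs[name] = _sha256(out / name)
    manifest.write_json(out / "manifest.json")
    logger.info("pipeline complete: %d outputs in %s", len(manifest.outputs), out)
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    echo = {}
    for key, value in vars(cfg).items():
        if isinstance(value, Path):
            echo[key] = str(value)
        elif isinstance(value, SimulationConfig):
            echo[key] = value.to_json_dict()
        else:
            echo[key] = value
    return echo
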