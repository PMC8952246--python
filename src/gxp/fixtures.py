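"""Deterministic synthetic-data generation.

Produces quantification tables (factor-encoded column names, lognormal
multiplicative noise around planted bin means), annotation tables (free
text, multi-valued bins, numeric log-fold-change consistent with the
planted differential expression), small sketch layouts, and a truth record
listing every planted effect so downstream tests can verify recovery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from gxp.errors import ValidationError
from gxp.mapman import SketchArea, SketchLayout
from gxp.tables_io import (
    AnnotationColumn,
    ExpressionMatrix,
    InfoTable,
    SampleKey,
    _atomic_write_text,
    parse_sample_name,
)

_BIN_VOCAB = ("1.1.1.1.1", "1.1.2", "1.3.4", "2.1", "9.1.4.2", "29.2.1.1")
_FAMILIES = ("kinase", "transporter", "transcription factor", "oxidase", "unknown")
_WORDS = (
    "putative", "membrane", "chloroplast", "ribosomal", "binding",
    "domain", "stress", "root", "leaf", "signalling",
)


@dataclass
class FixtureDesign:
    """Fully determines the generated dataset given its seed."""

    n_entities: int = 60
    group_levels: tuple[str, ...] = ("alpha", "beta")
    x_levels: tuple[str, ...] = ("ctrl", "cold", "salt", "heat")
    replicates: int = 3
    separator: str = "."
    unit: str = "TPM"
    noise_sd: float = 0.5  # log2-space sd of the multiplicative noise
    group_shift_sds: float = 5.0  # between-group shift, in noise-sd units
    n_de: int = 10  # entities differentially expressed in de_x_level
    de_x_level: str = "cold"
    de_shift_range: tuple[float, float] = (2.0, 4.0)  # planted log2 fold changes
    enriched_column: str = "mapman_bin"
    enriched_term: str = "9.1.4.2"
    enriched_in_selected: int = 8
    enriched_in_rest: int = 5
    search_phrase: str = "chalcone synthase"
    n_search_hits: int = 2
    seed: int = 42

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.n_entities < 1:
            raise ValidationError("need at least 1 entity")
        if self.n_de > self.n_entities:
            raise ValidationError("more DE entities than entities")
        if self.enriched_in_selected > self.n_de:
            raise ValidationError("enriched-in-selected exceeds DE set size")
        if self.enriched_in_rest > self.n_entities - self.n_de:
            raise ValidationError("enriched-in-rest exceeds non-DE set size")
        if self.de_x_level not in self.x_levels:
            raise ValidationError(f"de_x_level {self.de_x_level!r} not among x levels")
        if self.n_search_hits > self.n_entities:
            raise ValidationError("more search hits than entities")


@dataclass
class FixtureBundle:
    expression: ExpressionMatrix
    info: InfoTable
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.expression.to_tsv(os.path.join(out_dir, "quantification.tsv"))
        self.info.to_tsv(os.path.join(out_dir, "info.tsv"))
        _atomic_write_text(
            os.path.join(out_dir, "truth.json"),
            json.dumps(self.truth, indent=1, sort_keys=True) + "\n",
        )


def generate(design: FixtureDesign) -> FixtureBundle:
    """Generate one dataset; identical designs yield byte-identical files."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_entities
    entity_ids = [f"gene{i + 1:04d}" for i in range(n)]

    sample_names = []
    sample_keys = []
    for g in design.group_levels:
        for x in design.x_levels:
            for r in range(1, design.replicates + 1):
                name = design.separator.join([g, x, str(r)])
                sample_names.append(name)
                sample_keys.append(parse_sample_name(name, design.separator))

    # planted effects, all in log2 space
    base = rng.uniform(2.0, 10.0, size=n)
    group_shift = design.group_shift_sds * design.noise_sd
    group_dir = rng.choice([-1.0, 1.0], size=n)
    de_ids = sorted(rng.choice(n, size=design.n_de, replace=False).tolist())
    de_set = set(de_ids)
    de_shift = np.zeros(n)
    lo, hi = design.de_shift_range
    de_shift[de_ids] = rng.uniform(lo, hi, size=design.n_de)

    log2 = np.empty((n, len(sample_keys)))
    for j, key in enumerate(sample_keys):
        col = base.copy()
        if key.group_values and key.group_values[0] != design.group_levels[0]:
            col = col + group_dir * group_shift
        if key.x_value == design.de_x_level:
            col = col + de_shift
        col = col + rng.normal(0.0, design.noise_sd, size=n)
        log2[:, j] = col
    values = np.power(2.0, log2)  # bin mean times lognormal noise
    expression = ExpressionMatrix(
        entity_ids=entity_ids, samples=sample_keys, values=values, unit=design.unit
    )

    # ---- annotation columns -------------------------------------------------
    # log-fold-change column consistent with the planted shifts; non-DE values
    # stay strictly inside (-1, 1) so the threshold 1 recovers the DE set.
    log2fc = np.clip(rng.normal(0.0, 0.3, size=n), -0.9, 0.9)
    log2fc[de_ids] = de_shift[de_ids]

    enr_sel = sorted(rng.choice(de_ids, size=design.enriched_in_selected, replace=False).tolist())
    non_de = [i for i in range(n) if i not in de_set]
    enr_rest = sorted(rng.choice(non_de, size=design.enriched_in_rest, replace=False).tolist())
    enriched_members = set(enr_sel) | set(enr_rest)
    other_bins = [b for b in _BIN_VOCAB if b != design.enriched_term]
    bin_cells = []
    for i in range(n):
        picks = []
        if i in enriched_members:
            picks.append(design.enriched_term)
            if rng.random() < 0.3:
                picks.append(str(rng.choice(other_bins)))
        else:
            picks.append(str(rng.choice(other_bins)))
            if rng.random() < 0.2:
                extra = str(rng.choice(other_bins))
                if extra not in picks:
                    picks.append(extra)
        bin_cells.append(",".join(picks))

    family_cells = [str(rng.choice(_FAMILIES)) for _ in range(n)]

    search_rows = sorted(rng.choice(n, size=design.n_search_hits, replace=False).tolist())
    desc_cells = []
    for i in range(n):
        if i in search_rows:
            desc_cells.append(f"{design.search_phrase} homolog {i + 1}")
        else:
            w1, w2 = rng.choice(_WORDS, size=2, replace=True)
            desc_cells.append(f"{w1} {w2} protein {i + 1}")

    columns = {
        "description": AnnotationColumn(
            name="description", kind="text", cells=desc_cells
        ),
        "family": AnnotationColumn(
            name="family", kind="categorical", cells=family_cells, multivalue_delimiter=","
        ),
        "mapman_bin": AnnotationColumn(
            name="mapman_bin", kind="categorical", cells=bin_cells, multivalue_delimiter=","
        ),
        "log2FC_cold": AnnotationColumn(
            name="log2FC_cold", kind="numeric", cells=[float(v) for v in log2fc]
        ),
    }
    info = InfoTable(entity_ids=entity_ids, columns=columns)

    group_partition = {
        g: [k.raw_name for k in sample_keys if k.group_values == (g,)]
        for g in design.group_levels
    }
    truth = {
        "seed": design.seed,
        "sample_names": sample_names,
        "x_levels": list(design.x_levels),
        "group_levels": list(design.group_levels),
        "replicates": design.replicates,
        "unit": design.unit,
        "separator": design.separator,
        "group_partition": group_partition,
        "column_kinds": {name: c.kind for name, c in columns.items()},
        "de_ids": [entity_ids[i] for i in de_ids],
        "de_shifts": {entity_ids[i]: float(de_shift[i]) for i in de_ids},
        "de_x_level": design.de_x_level,
        "selection": {"column": "log2FC_cold", "comparator": ">", "threshold": 1.0},
        "enriched": {
            "column": design.enriched_column,
            "term": design.enriched_term,
            "selected_members": [entity_ids[i] for i in enr_sel],
            "background_members": [entity_ids[i] for i in enr_rest],
        },
        "search": {
            "phrase": design.search_phrase,
            "ids": [entity_ids[i] for i in search_rows],
        },
    }
    return FixtureBundle(expression=expression, info=info, truth=truth)


def ora_design(seed: int = 42) -> FixtureDesign:
    """Larger design for overrepresentation power checks: 200 background
    entities, 40 selected, enriched term covering 30 selected + 10 others."""
    return FixtureDesign(
        n_entities=200,
        n_de=40,
        enriched_in_selected=30,
        enriched_in_rest=10,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# built-in sketch layouts
# ---------------------------------------------------------------------------


def builtin_layout(name: str) -> SketchLayout:
    """Small hand-made layouts exercising the full bin-matching logic."""
    if name == "photosynthesis_mini":
        return SketchLayout(
            name="photosynthesis_mini",
            canvas_width=480,
            canvas_height=320,
            areas=[
                SketchArea("lhc", "1.1", 40, 50, 6, "light reactions"),
                SketchArea("calvin", "1.3", 40, 160, 6, "Calvin cycle"),
                SketchArea("photorespiration", "1.2", 260, 50, 6, "photorespiration"),
            ],
        )
    if name == "metabolism_overview_mini":
        return SketchLayout(
            name="metabolism_overview_mini",
            canvas_width=640,
            canvas_height=420,
            areas=[
                SketchArea("photosynthesis", "1", 40, 50, 8, "photosynthesis"),
                SketchArea("major_cho", "2.1", 40, 200, 6, "major CHO metabolism"),
                SketchArea("secondary", "9.1", 300, 50, 6, "secondary metabolism"),
                SketchArea("secondary_n", "9.1.4", 300, 200, 6, "N-containing secondary"),
                SketchArea("protein", "29.2", 480, 200, 6, "protein synthesis"),
            ],
        )
    raise ValidationError(f"unknown built-in layout {name!r}")


BUILTIN_LAYOUTS = ("metabolism_overview_mini", "photosynthesis_mini")
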