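"""Synthetic per-sample congener concentration tables.

The reference survey published only group-level summaries (min/max/mean/SD
per congener), not raw samples, so analyses are exercised on synthetic
tables with the same statistical structure: each congener is drawn from a
lognormal calibrated so that, after truncation to the printed [min, max]
window, its mean matches the printed mean exactly and its SD as closely as
the window allows. Draws use rejection sampling and one labeled random
stream per (group, congener), so the tables are bit-reproducible for a
fixed seed and insensitive to the presence of other streams.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .congeners import BRANDS, CONGENERS, Congener
from .distributions import MomentSpec
from .errors import GenerationError, InvalidParameterError
from .exposure import generate_exposure_draws, stream_rng  # re-exported

__all__ = [
    "ProductSpec",
    "generate_samples",
    "generate_survey",
    "generate_exposure_draws",
    "SAMPLE_COLUMNS",
]

#: Canonical column order of a sample table.
SAMPLE_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "product",
    "brand",
    *(c.value for c in CONGENERS),
)


@dataclasses.dataclass(frozen=True)
class ProductSpec:
    """Generation recipe for one group of samples.

    ``brand`` may be empty (unspecified). All six congeners must carry a
    :class:`MomentSpec`; ``n_samples`` must be at least 2.
    """

    product: str
    congener_specs: Mapping[Congener, MomentSpec]
    n_samples: int
    brand: str = ""

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidParameterError(f"n_samples must be >= 2, got {self.n_samples}")
        missing = [c for c in CONGENERS if c not in self.congener_specs]
        if missing:
            raise InvalidParameterError(
                f"congener_specs missing {[c.value for c in missing]}"
            )
        object.__setattr__(self, "congener_specs", dict(self.congener_specs))


def _draw_congener(spec: MomentSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    from .distributions import sample_truncated_lognormal

    if spec.maximum < spec.minimum:
        raise GenerationError(
            f"infeasible bounds: maximum {spec.maximum} < minimum {spec.minimum}"
        )
    if spec.sd == 0.0:
        return np.full(n, spec.mean)
    return sample_truncated_lognormal(spec.fit(), spec.minimum, spec.maximum, n, rng)


def generate_samples(spec: ProductSpec, seed: int) -> pd.DataFrame:
    """Generate ``spec.n_samples`` records for one product (and brand) group.

    Returns a table with the canonical columns; concentrations in ng/g fat,
    strictly positive and inside each congener's [minimum, maximum].
    """
    group = f"{spec.product}:{spec.brand}"
    data: dict[str, object] = {
        "sample_id": [f"{spec.product}{'-' + spec.brand if spec.brand else ''}-{i + 1:05d}"
                      for i in range(spec.n_samples)],
        "product": spec.product,
        "brand": spec.brand,
    }
    for cong in CONGENERS:
        rng = stream_rng(seed, "samples", group, cong.value)
        data[cong.value] = _draw_congener(spec.congener_specs[cong], spec.n_samples, rng)
    return pd.DataFrame(data, columns=list(SAMPLE_COLUMNS))


def generate_survey(
    product_specs: Mapping[str, Mapping[Congener, MomentSpec]],
    n_per_product: int = 40,
    seed: int = 0,
    brands: Sequence[str] = BRANDS,
) -> pd.DataFrame:
    """Generate a full multi-product survey table.

    One group of ``n_per_product`` samples per product type, drawn from that
    product's moment specs. Brand labels partition each product's samples
    into equal contiguous shares (the brand-by-product allocation of the
    reference survey was not published; labels are assigned, not modeled),
    so brand-level grouping operations have data to act on.
    """
    frames = []
    for product, specs in product_specs.items():
        frame = generate_samples(
            ProductSpec(product=product, congener_specs=specs, n_samples=n_per_product),
            seed=seed,
        )
        if brands:
            reps = int(np.ceil(n_per_product / len(brands)))
            labels = np.repeat(list(brands), reps)[:n_per_product]
            frame = frame.assign(brand=labels)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
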