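"""Adapters between fitted-model objects and the generic ModelContainer."""

from __future__ import annotations

from .io import ModelContainer, ValidationError
from .miso import SrspModel
from .rate import RateDecoder
from .rotation import ProjectionPlane

__all__ = [
    "srsp_to_container",
    "srsp_from_container",
    "decoder_to_container",
    "decoder_from_container",
    "planes_to_container",
    "planes_from_container",
]


def srsp_to_container(model: SrspModel, metadata: dict | None = None) -> ModelContainer:
    md = dict(metadata or {})
    md.update(
        bin_width=model.bin_width,
        ridge=model.ridge,
        unit_ids=list(map(str, model.unit_ids)),
        channel_ids=list(map(str, model.channel_ids)),
    )
    return ModelContainer(
        model_kind="srsp",
        metadata=md,
        payload={
            "kernels": model.kernels,
            "lags": model.lags,
            "offsets": model.offsets,
            "vaf": model.vaf,
        },
    )


def srsp_from_container(c: ModelContainer) -> SrspModel:
    if c.model_kind != "srsp":
        raise ValidationError(f"expected an srsp container, got {c.model_kind!r}")
    return SrspModel(
        kernels=c.payload["kernels"],
        lags=c.payload["lags"],
        bin_width=float(c.metadata["bin_width"]),
        offsets=c.payload["offsets"],
        ridge=float(c.metadata["ridge"]),
        unit_ids=list(c.metadata["unit_ids"]),
        channel_ids=list(c.metadata["channel_ids"]),
        vaf=c.payload["vaf"],
    )


def decoder_to_container(dec: RateDecoder, metadata: dict | None = None) -> ModelContainer:
    md = dict(metadata or {})
    md.update(
        nsr=dec.nsr,
        bin_width=dec.bin_width,
        unit_ids=list(map(str, dec.unit_ids)),
        channel_ids=list(map(str, dec.channel_ids)),
    )
    return ModelContainer(
        model_kind="rate_decoder",
        metadata=md,
        payload={
            "filters": dec.filters,
            "filter_lags": dec.filter_lags,
            "offsets": dec.offsets,
            "channel_means": dec.channel_means,
        },
    )


def decoder_from_container(c: ModelContainer) -> RateDecoder:
    if c.model_kind != "rate_decoder":
        raise ValidationError(f"expected a rate_decoder container, got {c.model_kind!r}")
    return RateDecoder(
        filters=c.payload["filters"],
        filter_lags=c.payload["filter_lags"],
        offsets=c.payload["offsets"],
        channel_means=c.payload["channel_means"],
        nsr=float(c.metadata["nsr"]),
        bin_width=float(c.metadata["bin_width"]),
        unit_ids=list(c.metadata["unit_ids"]),
        channel_ids=list(c.metadata["channel_ids"]),
    )


def planes_to_container(planes: list, metadata: dict | None = None) -> ModelContainer:
    md = dict(metadata or {})
    md.update(
        kinds=[p.kind for p in planes],
        freqs=[None if p.freq_hz is None else float(p.freq_hz) for p in planes],
        has_offset=[p.offset is not None for p in planes],
    )
    payload = {}
    for i, p in enumerate(planes):
        payload[f"u{i}"] = p.u
        payload[f"v{i}"] = p.v
        if p.offset is not None:
            payload[f"offset{i}"] = p.offset
    return ModelContainer(model_kind="rotation", metadata=md, payload=payload)


def planes_from_container(c: ModelContainer) -> list:
    if c.model_kind != "rotation":
        raise ValidationError(f"expected a rotation container, got {c.model_kind!r}")
    planes = []
    for i, kind in enumerate(c.metadata["kinds"]):
        planes.append(
            ProjectionPlane(
                u=c.payload[f"u{i}"],
                v=c.payload[f"v{i}"],
                kind=kind,
                freq_hz=c.metadata["freqs"][i],
                offset=c.payload.get(f"offset{i}"),
            )
        )
    return planes
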