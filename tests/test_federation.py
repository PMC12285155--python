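"""FedAvg aggregation, federated training/correction, held-out clients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedbatch.data import partition_by_batch
from fedbatch.federation import (
    FederationConfig,
    apply_public_means,
    client_stream_seed,
    export_public_means,
    fedavg,
    federated_correction,
    federated_train,
    global_type_sharing,
)
from fedbatch.scgen import compute_type_means, correct_latent, identify_sharing
from fedbatch.vae import VAEParams, encode, init_vae, params_digest, train_local


def _scalar_params(*values):
    return [VAEParams({"w": np.asarray([float(v)])}) for v in values]


class TestFedAvg:
    def test_single_client_identity(self):
        (p,) = _scalar_params(3.25)
        out = fedavg([p], [17.0])
        np.testing.assert_array_equal(out["w"], p["w"])

    def test_symmetry_cancels(self):
        p, q = _scalar_params(2.5, -2.5)
        np.testing.assert_allclose(fedavg([p, q], [1.0, 1.0])["w"], [0.0])

    def test_weighted_combination(self):
        p, q = _scalar_params(0.0, 4.0)
        np.testing.assert_allclose(fedavg([p, q], [1.0, 3.0])["w"], [3.0])

    def test_shape_mismatch_rejected(self):
        p = VAEParams({"w": np.zeros(2)})
        q = VAEParams({"w": np.zeros(3)})
        with pytest.raises(ValueError):
            fedavg([p, q], [1.0, 1.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_within_client_envelope(self, seed):
        rng = np.random.default_rng(seed)
        ps = [VAEParams({"w": rng.normal(size=4)}) for _ in range(3)]
        ws = rng.uniform(0.5, 10, size=3).tolist()
        out = fedavg(ps, ws)["w"]
        stacked = np.stack([p["w"] for p in ps])
        assert (out >= stacked.min(axis=0) - 1e-12).all()
        assert (out <= stacked.max(axis=0) + 1e-12).all()


class TestFederatedTraining:
    def test_single_client_equals_centralized(self, small_prepped, tiny_vae_config):
        clients = partition_by_batch(small_prepped)[:1]
        fed = FederationConfig(n_rounds=3, local_epochs=2, seed=7)
        global_params, _ = federated_train(clients, fed, tiny_vae_config)

        central, _, _ = train_local(
            init_vae(tiny_vae_config),
            clients[0].dataset,
            6,
            tiny_vae_config,
            seed=client_stream_seed(7, clients[0].client_id),
        )
        assert params_digest(global_params) == params_digest(central)

    def test_round_log_schema(self, small_prepped, tiny_vae_config):
        clients = partition_by_batch(small_prepped)
        _, logs = federated_train(
            clients, FederationConfig(n_rounds=2, local_epochs=1, seed=0), tiny_vae_config
        )
        client_rows = [r for r in logs if r["client"] is not None]
        assert len(client_rows) == 2 * len(clients)
        assert all({"round", "client", "loss", "n_cells", "digest"} <= set(r) for r in client_rows)

    def test_identical_clients_equal_single_client(self, small_prepped, tiny_vae_config):
        # same data on both clients and matched streams -> aggregation is a no-op
        from fedbatch.data import ClientPartition

        base = small_prepped.subset_cells(small_prepped.batch_labels == "B0")
        # same client_id -> same minibatch stream on both replicas
        clients = [
            ClientPartition(client_id=0, dataset=base, batch="X0"),
            ClientPartition(client_id=0, dataset=base, batch="X1"),
        ]
        fed = FederationConfig(n_rounds=2, local_epochs=1, seed=3)
        params, _ = federated_train(clients, fed, tiny_vae_config)
        solo, _ = federated_train(clients[:1], fed, tiny_vae_config)
        assert params_digest(params) == params_digest(solo)

    def test_empty_client_list_rejected(self, tiny_vae_config):
        with pytest.raises(ValueError):
            federated_train([], FederationConfig(), tiny_vae_config)

    def test_invalid_round_count_rejected(self):
        with pytest.raises(ValueError):
            FederationConfig(n_rounds=0)


class TestGlobalSharing:
    def test_agrees_with_centralized_on_pooled_data(self, small_prepped):
        clients = partition_by_batch(small_prepped)
        fed_sharing = global_type_sharing(clients)
        central = identify_sharing(small_prepped)
        assert fed_sharing.shared == central.shared
        assert fed_sharing.standalone == central.standalone


class TestFederatedCorrection:
    def test_matches_centralized_correction(self, small_prepped, trained_model):
        clients = partition_by_batch(small_prepped)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))

        Z = encode(trained_model, small_prepped.matrix)
        means = compute_type_means(trained_model, small_prepped)
        Zc = correct_latent(
            Z, small_prepped.cell_type_labels, small_prepped.batch_labels.astype(str), means
        )
        for c in clients:
            sel = small_prepped.batch_labels == c.batch
            np.testing.assert_allclose(result.latents_corrected[c.client_id], Zc[sel], atol=1e-8)
        for t in means.types():
            np.testing.assert_allclose(result.mean_map.means[t], means.means[t], atol=1e-10)
            assert result.mean_map.dominant_batch[t] == means.dominant_batch[t]

    def test_one_client_federation_is_centralized(self, small_prepped, trained_model):
        solo = small_prepped.subset_cells(small_prepped.batch_labels == "B0")
        clients = partition_by_batch(solo)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))
        # all types standalone on one client: latents unchanged
        np.testing.assert_array_equal(result.latents[0], result.latents_corrected[0])

    def test_coordinator_transcript_has_no_raw_data(self, small_prepped, trained_model):
        clients = partition_by_batch(small_prepped)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))
        n_latent = trained_model["enc_mu_b"].shape[0]
        for msg in result.transcript.seen_by("coordinator"):
            payload = msg["payload"]
            if isinstance(payload, dict) and "mean" in payload:
                assert np.asarray(payload["mean"]).size == n_latent  # a centroid, not cells


class TestHeldOut:
    def test_nondominating_held_out_leaves_means_unchanged(self, small_prepped, trained_model):
        from fedbatch.data import ClientPartition

        clients = partition_by_batch(small_prepped)
        base = federated_correction(clients, trained_model, FederationConfig(seed=0))
        # tiny new batch: 3 cells of each type, never dominant
        rng = np.random.default_rng(1)
        idx = np.concatenate(
            [np.flatnonzero(small_prepped.cell_type_labels == t)[:3]
             for t in small_prepped.cell_types()]
        )
        newcomer = small_prepped.subset_cells(idx)
        newcomer.batch_labels = np.asarray(["B9"] * len(idx), dtype=object)
        extended = clients + [ClientPartition(client_id=9, dataset=newcomer, batch="B9")]
        ext = federated_correction(extended, trained_model, FederationConfig(seed=0))
        assert ext.mean_map.dominant_batch == base.mean_map.dominant_batch
        for t in base.mean_map.types():
            np.testing.assert_allclose(ext.mean_map.means[t], base.mean_map.means[t], atol=1e-10)

    def test_dominating_held_out_updates_exactly_its_types(self, small_prepped, trained_model):
        from fedbatch.data import ClientPartition, concatenate
        from fedbatch.scgen import dominant_batch_for

        clients = partition_by_batch(small_prepped)
        # newcomer holds more alpha cells than any existing batch
        alpha_idx = np.flatnonzero(small_prepped.cell_type_labels == "alpha")
        take = np.concatenate([alpha_idx, alpha_idx])[:41]
        newcomer = small_prepped.subset_cells(take)
        newcomer.batch_labels = np.asarray(["B9"] * len(take), dtype=object)
        newcomer.cell_ids = np.asarray([f"n{i}" for i in range(len(take))], dtype=object)
        extended = clients + [ClientPartition(client_id=9, dataset=newcomer, batch="B9")]
        result = federated_correction(extended, trained_model, FederationConfig(seed=0))
        assert result.mean_map.dominant_batch["alpha"] == "B9"

        # pooled-data oracle: centralized means on the concatenated dataset
        pooled = concatenate([small_prepped, newcomer])
        assert dominant_batch_for(pooled, "alpha") == ("B9", 41)
        oracle = compute_type_means(trained_model, pooled)
        for t in result.mean_map.types():
            np.testing.assert_allclose(result.mean_map.means[t], oracle.means[t], atol=1e-8)


class TestPublicMeansExport:
    def test_artifact_round_trips_and_contains_no_cells(self, small_prepped, trained_model):
        import json

        clients = partition_by_batch(small_prepped)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))
        artifact = json.loads(json.dumps(export_public_means(result)))
        assert artifact["n_cells"] == 0
        assert set(artifact["types"]) == set(map(str, result.mean_map.types()))

    def test_fresh_client_correction_matches_federated(self, small_prepped, trained_model):
        clients = partition_by_batch(small_prepped)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))
        artifact = export_public_means(result)
        c = clients[1]
        corrected, Zc = apply_public_means(artifact, trained_model, c.dataset)
        np.testing.assert_allclose(Zc, result.latents_corrected[c.client_id], atol=1e-10)
        np.testing.assert_allclose(
            corrected.matrix, result.corrected[c.client_id].matrix, atol=1e-8
        )

    def test_wrong_model_rejected(self, small_prepped, trained_model, tiny_vae_config):
        clients = partition_by_batch(small_prepped)
        result = federated_correction(clients, trained_model, FederationConfig(seed=0))
        artifact = export_public_means(result)
        other = init_vae(tiny_vae_config)
        with pytest.raises(ValueError, match="different model"):
            apply_public_means(artifact, other, clients[0].dataset)
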