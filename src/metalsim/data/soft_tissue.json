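{"name": "soft_tissue", "density_g_cm3": 1.06, "source": "standard reference photon mass attenuation table, 4-component soft tissue (approximate)"}
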