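{"name": "water", "density_g_cm3": 1.0, "source": "standard reference photon mass attenuation table (with coherent scattering)"}
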