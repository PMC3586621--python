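locality,established_from_year,note
Auckland,,core of the established invaded range since the mid-1960s
Whangarei,,northern North Island established range
Hamilton,,northern North Island established range
Tauranga,,Bay of Plenty established range
Waihi Beach,,western Bay of Plenty established range
Palmerston North,2007,emerging population; include only for analyses dated 2007 or later
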