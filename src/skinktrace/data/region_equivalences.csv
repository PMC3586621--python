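locality_a,locality_b,tier,note
Gold Coast,Gold Coast-Lamington NP,exact,same region; Lamington NP lies in the Gold Coast hinterland
Caboolture,Brisbane (North),exact,Caboolture borders the northern suburbs of Brisbane
Brisbane (Samford),Brisbane (North),exact,Samford lies on Brisbane's north-western outskirts
Bega NSW,NSW/VIC border region,exact,Bega is in far south-eastern NSW near the Victorian border
Eden NSW,NSW/VIC border region,exact,Eden is in far south-eastern NSW near the Victorian border
Melbourne,Melbourne region,exact,same region
Brisbane,Gold Coast-Lamington NP,near,Gold Coast is approximately 80 km from Brisbane
Sydney,North NSW coast-Wyong,near,Wyong is approximately 90 km from Sydney
North Sydney,North NSW coast-Wyong,near,Wyong is approximately 90 km north of Sydney
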