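>H2A canonical Xenopus laevis H2A (core-histone reference numbering)
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAVRNDEELNKLLGGVTIAQGGVLPNIQSVLLPKKT
ESSKSKSK
>H2A.Z canonical Homo sapiens H2A.Z
AGGKAGKDSGKAKTKAVSRSQRAGLQFPVGRIHRHLKSRTTSHGRVGATAAVYSAAILEY
LTAEVLELAGNASKDLKVKRITPRHLQLAIRGDEELDSLIKATIAGGGVIPHIHKSLIGK
KGQQKTV
>H2B canonical Xenopus laevis H2B
PEPAKSAPAPKKGSKKAVTKTQKKDGKKRKRSRKESYAIYVYKVLKQVHPDTGISSKAMS
IMNSFVNDVFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTK
YTSAK
>H3 canonical Xenopus laevis H3
ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTEL
LIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIM
PKDIQLARRIRGERA
>H4 canonical Xenopus laevis H4
SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKV
FLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
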