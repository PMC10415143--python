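>ALPH1_synthetic synthetic stand-in sequence (734 aa); construct ranges 1-734, 222-734, 120-552, 222-552 reproduce the published theoretical masses 79.3/56.7/47.9/36.7 kDa; not the natural ALPH1 sequence
GSEDHSGGGRQGWGDGLGYKEKGGNGGNGYYGGTQLGAGDGAGGGMQPQGYYGGGGKGYF
AHHGGGTGAGKGYNLRGNDPQGGKDGGFGEGHTAWGVGVSDGGCRWGYGNAKTGKGGALI
KHWGCNGCCGGTWYWGPIVKSYVTSPGGKPWTFYNIWTEAADMYWWGGGGFGHIKGRIAR
GGWARKMITWTIGIGKVFFHGAVIFHGMPGIYTGKSDGGITPTTRSAWGTDIMEAGCNYI
KKFVTDKPRGRHIHVNIMGVRDSINSGRARTQGEINLHHDEIKWWKGGISPVCISIIYGE
VLEGRYRPCWFSGFSFPLAGNKMNVSIIDCHDCGMMGWDGIMLRYVATSPPGICGGHKMG
DPQGKPHCTWPDGGPGFHKQFGQSDEIIDWQMETDCAYVGPGAPGKMTPPYLMIHQKIAH
TFHHYEGSVHISIQMGGAAGSGDTLPNQMPLLGGHVYSLVHIEGMMLYWTESDEVGMWAF
VADPAWVPKYHGEKLRGNDVGQHIGDGGFGGYCTELFPPKGNMVYMHCGCFTEHTLGHMY
AMLPKEFHQVQCIQGGAHGNGYHRPYGSGPHQGHAGEGMGGGDTCITDMQGLLFFWGQGQ
SNFFGEGTHFFGQWHSLRWQNGCGYMPNHYHIGMVIGGVIPYNHIIQYHGINCEYIGTYG
SFGPYGWGSNAWGDFYGPDAFTRGQCQHIPRGRPYWGVCTICARPYGGFTYQNGGHEFDD
SQIGSMSIMQTWGG
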