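{
  "COHORT1_gene_counts.tsv": "fb8944bbd03ab124021e30aba07abb048311d4aa6c190f5ba303d62352d0d37c",
  "COHORT1_isoform_quant.tsv": "b9bd3f90b1002cad9e25914c1a6cdb8915e10e8e453d3e2dc4cbdb40f1831c82",
  "COHORT2_gene_counts.tsv": "3154725b2e5bd4b8cac499286cd159da0005c3c16e6c8ed39078a5acb1f2310f",
  "COHORT2_isoform_quant.tsv": "eff0901c9df511946318a5172a1cf24e605914d755bd096f379642e84b7aed08",
  "COHORT3_gene_counts.tsv": "ded1ac479d9e269226325d82d4df4f55e9889dd3fee01bf17d4c41b6a1a9c334",
  "COHORT3_isoform_quant.tsv": "a0e36adf9bf1f3d476da9c4f91a695d7a633c5933c9e1aea0f63cb6c1adac498",
  "config.yaml": "76c3b1aa16076191465dc14bae48ad3e6471b799637d0eb63d2f0e8b689bbf31",
  "gene_lengths.tsv": "48003dee954a6d18c07a5e73bc8f1a488f05dae0095b2137de850eb558733829",
  "gene_sets.gmt": "7c0f34428872e848aba9107c77bf6a87e57d55498bb47580438d8c3d82a42799",
  "hairpins.fa": "754294ec8d01906c807834e3fc8efaa6a82b1cd61b2208743793e014bded2c28",
  "mirdb_predictions.tsv": "d5fb47b0eacacd359b62e42d0108db2e2e270b9eefc3ffbdc060896ed448b4bf",
  "mirna.gff3": "33436e0674a077001187bd194ee7ccc8bc5a8e860b9be21221077d1294446a2f",
  "results/COHORT1/gene_log2_tmm_fpkm.tsv": "efd4cef7192a30f0659a9b3686c933eddf6a0cd9b41d75bcea3dac904bfcebc5",
  "results/COHORT1/highly_expressed.txt": "009bbcbd8321acc6375041fa09bebac347d3764b6ce33781ad1197a0656dfbb4",
  "results/COHORT1/interactions.tsv": "2d7b9ad1b52c2c2ab4370791f9fa56cbf76a0c91db6b44ca23cc6b9b403a7320",
  "results/COHORT1/isomir_log2_tmm_rpm.tsv": "631238d3702aef2ec3671b16f941bed6328d42607c1634e77b3a38ded7cfbc48",
  "results/COHORT1/ita.tsv": "fb4d1baee8f6ee392765ff036ecfccf81a39bdea584613c53e08bd1ca3bbde99",
  "results/COHORT1/modules.json": "db6d56d7379234edf87682abb183b22de97b25e844387d918b9b487e0fe25024",
  "results/COHORT1/ora.tsv": "10a1c6372bfb939b7a641ce1dc77f2035747dc36160625a694ccd6bdfb71aa9f",
  "results/COHORT1/run_report.json": "0dcf1d9fb23e6dbd732c4477045e34fc4bbb14a3938a860e844927779a6f40a5",
  "results/COHORT1/targetomes.tsv": "28343076ae2494e12c90aff855e4b90d2760a4de36247afcc69afff3964f52a4",
  "results/COHORT2/gene_log2_tmm_fpkm.tsv": "65807ca747db6b9e466254ce8c61ebf34624dfc0229d2fec93236f804d8969ae",
  "results/COHORT2/highly_expressed.txt": "ee17c7be3996a49ecaeebab78b014372b19e6181a9df2baa44c6c3bde963bad3",
  "results/COHORT2/interactions.tsv": "79940aa7e13e20e6df876ffb9d48a40536d9b8b9a4185ffa432972631ab5c40e",
  "results/COHORT2/isomir_log2_tmm_rpm.tsv": "7b0d176012e46df15355ed60942b8d693def467d58c7887a223e3a34bdff120f",
  "results/COHORT2/ita.tsv": "7e3c0dda829f0900d93166edf71e85387ebdea0fa42173bcbd424365a2409f50",
  "results/COHORT2/modules.json": "8dd825654b078614d502550176870b6023fe010439305027143cff712e7322bd",
  "results/COHORT2/ora.tsv": "752463b4a2d342a038ef9ec141799faf79aface3127148a6250fc90026f1d578",
  "results/COHORT2/run_report.json": "5dd41523bee11be938c37bb56159d9c21fae1af14f5effc0e44035fc6e8dcd0f",
  "results/COHORT2/targetomes.tsv": "28343076ae2494e12c90aff855e4b90d2760a4de36247afcc69afff3964f52a4",
  "results/COHORT3/gene_log2_tmm_fpkm.tsv": "9ff26838cfd0c62743ce26f9772887bd23a879ee1777a61f671b1cb05d52990e",
  "results/COHORT3/highly_expressed.txt": "4f0be40c44ab2ea031d8ef4c8653b4a96301882b5394ca701b04b2141653d325",
  "results/COHORT3/interactions.tsv": "4f87fd95074bb9ed16284e851dc1899fa30ad3f430d0b3484e033eb3a98232d0",
  "results/COHORT3/isomir_log2_tmm_rpm.tsv": "e4a3fbf2dcb53024139e2f025598bc67de872d8dd9e165f9393ccba5bb005fe5",
  "results/COHORT3/ita.tsv": "f290f069cc7ac30df42d2bdd1717b32197aee1a4c94c6552c96860e463a79af9",
  "results/COHORT3/modules.json": "f8e7beaf50b5f251ca75650425975fcceb3605264d442871312202b051ae05f9",
  "results/COHORT3/ora.tsv": "ab96f84deb737e1f4a235d5e561261a48a3569dc4628aac554f2449e4ca06240",
  "results/COHORT3/run_report.json": "d793b2408890c19331ce25606ec83fd78748db792366e8644464ca67086f8761",
  "results/COHORT3/targetomes.tsv": "28343076ae2494e12c90aff855e4b90d2760a4de36247afcc69afff3964f52a4",
  "results/pancancer/adjacent_jaccard.tsv": "448864f7029f7a39cf13259e317e23bc402ca727b022ecd5e94cc1dd913a363b",
  "results/pancancer/adjacent_summary.json": "d0f0d98ad4ba4a9d6cd24bf158c524fe8298711bc800e2b9da1c931e421cc4a0",
  "results/pancancer/highly_expressed_matrix.tsv": "8f68c9a39992d0d4bbaa87465779b530700fa3e56ab7e267768c71e6e35f912f",
  "results/pancancer/pancancer_ita.tsv": "428a61b0e49c50365afc63df686011df4a2907ac8f78e929f5b5d11b1b28451c",
  "results/pancancer/pancancer_report.json": "b7fc24dbcc977960db08075fc6c118b315430f4d0d73fce0525c9ded607d1f48",
  "results/pancancer/universal_network.json": "782eb7edc56c3ef0a8cdc57b315b66b85bdebfa3f832172f7d4d88b77fa55db6",
  "targetscan_predictions.tsv": "e25c165a02d55ff0d69b22cb492c58f053ad9fbc515241d10c4de28cbf31584d",
  "truth.json": "266b44986e0774d78f9f9d8ca2d2f01b1d2ccd9332d13ea82b89adafcd396cad"
}
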